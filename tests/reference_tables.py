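"""Second, independent transcription of the REBA / RULA / OWAS lookup tables.

These grids are laid out the way the published instrument sheets print them
(row-per-posture, column blocks per modifier), deliberately different from
the long-format CSVs shipped in the package, so that a transposition or
off-by-one slip in either copy shows up as a mismatch in the exhaustive
comparison tests.
"""

import numpy as np

# REBA Table A — rows: trunk 1-5; column blocks: neck 1-3, each legs 1-4.
_REBA_A_SHEET = [
    # neck 1          neck 2          neck 3
    [1, 2, 3, 4,      1, 2, 3, 4,     3, 3, 5, 6],   # trunk 1
    [2, 3, 4, 5,      3, 4, 5, 6,     4, 5, 6, 7],   # trunk 2
    [2, 4, 5, 6,      4, 5, 6, 7,     5, 6, 7, 8],   # trunk 3
    [3, 5, 6, 7,      5, 6, 7, 8,     6, 7, 8, 9],   # trunk 4
    [4, 6, 7, 8,      6, 7, 8, 9,     7, 8, 9, 9],   # trunk 5
]

# REBA Table B — rows: upper arm 1-6; column blocks: lower arm 1-2, each wrist 1-3.
_REBA_B_SHEET = [
    # lower arm 1   lower arm 2
    [1, 2, 2,       1, 2, 3],   # upper arm 1
    [1, 2, 3,       2, 3, 4],   # upper arm 2
    [3, 4, 5,       4, 5, 5],   # upper arm 3
    [4, 5, 5,       5, 6, 7],   # upper arm 4
    [6, 7, 8,       8, 8, 9],   # upper arm 5
    [7, 8, 8,       8, 9, 9],   # upper arm 6
]

# REBA Table C — rows: score A 1-12; columns: score B 1-12.
_REBA_C_SHEET = [
    [1, 1, 1, 2, 3, 3, 4, 5, 6, 7, 7, 7],
    [1, 2, 2, 3, 4, 4, 5, 6, 6, 7, 7, 8],
    [2, 3, 3, 3, 4, 5, 6, 7, 7, 8, 8, 8],
    [3, 4, 4, 4, 5, 6, 7, 8, 8, 9, 9, 9],
    [4, 4, 4, 5, 6, 7, 8, 8, 9, 9, 9, 9],
    [6, 6, 6, 7, 8, 8, 9, 9, 10, 10, 10, 10],
    [7, 7, 7, 8, 9, 9, 9, 10, 10, 11, 11, 11],
    [8, 8, 8, 9, 10, 10, 10, 10, 10, 11, 11, 11],
    [9, 9, 9, 10, 10, 10, 11, 11, 11, 12, 12, 12],
    [10, 10, 10, 11, 11, 11, 11, 12, 12, 12, 12, 12],
    [11, 11, 11, 11, 12, 12, 12, 12, 12, 12, 12, 12],
    [12, 12, 12, 12, 12, 12, 12, 12, 12, 12, 12, 12],
]

# RULA Table A — rows: (upper arm, lower arm) in sheet order; columns: wrist 1-4,
# each (twist 1, twist 2).
_RULA_A_SHEET = [
    [1, 2, 2, 2, 2, 3, 3, 3],   # UA1 LA1
    [2, 2, 2, 2, 3, 3, 3, 3],   # UA1 LA2
    [2, 3, 3, 3, 3, 3, 4, 4],   # UA1 LA3
    [2, 3, 3, 3, 3, 4, 4, 4],   # UA2 LA1
    [3, 3, 3, 3, 3, 4, 4, 4],   # UA2 LA2
    [3, 4, 4, 4, 4, 4, 5, 5],   # UA2 LA3
    [3, 3, 4, 4, 4, 4, 5, 5],   # UA3 LA1
    [3, 4, 4, 4, 4, 4, 5, 5],   # UA3 LA2
    [4, 4, 4, 4, 4, 5, 5, 5],   # UA3 LA3
    [4, 4, 4, 4, 4, 5, 5, 5],   # UA4 LA1
    [4, 4, 4, 4, 4, 5, 5, 5],   # UA4 LA2
    [4, 4, 4, 5, 5, 5, 6, 6],   # UA4 LA3
    [5, 5, 5, 5, 5, 6, 6, 7],   # UA5 LA1
    [5, 6, 6, 6, 6, 7, 7, 7],   # UA5 LA2
    [6, 6, 6, 7, 7, 7, 7, 8],   # UA5 LA3
    [7, 7, 7, 7, 7, 8, 8, 9],   # UA6 LA1
    [8, 8, 8, 8, 8, 9, 9, 9],   # UA6 LA2
    [9, 9, 9, 9, 9, 9, 9, 9],   # UA6 LA3
]

# RULA Table B — rows: neck 1-6; columns: trunk 1-6, each (legs 1, legs 2).
_RULA_B_SHEET = [
    [1, 3, 2, 3, 3, 4, 5, 5, 6, 6, 7, 7],
    [2, 3, 2, 3, 4, 5, 5, 5, 6, 7, 7, 7],
    [3, 3, 3, 4, 4, 5, 5, 6, 6, 7, 7, 7],
    [5, 5, 5, 6, 6, 7, 7, 7, 7, 7, 8, 8],
    [7, 7, 7, 7, 7, 8, 8, 8, 8, 8, 8, 8],
    [8, 8, 8, 8, 8, 8, 8, 9, 9, 9, 9, 9],
]

# RULA Table C — rows: score A 1-8 (8 = "8+"); columns: score B 1-7 (7 = "7+").
_RULA_C_SHEET = [
    [1, 2, 3, 3, 4, 5, 5],
    [2, 2, 3, 4, 4, 5, 5],
    [3, 3, 3, 4, 4, 5, 6],
    [3, 3, 3, 4, 5, 6, 6],
    [4, 4, 4, 5, 6, 7, 7],
    [4, 4, 5, 6, 6, 7, 7],
    [5, 5, 6, 6, 7, 7, 7],
    [5, 5, 6, 7, 7, 7, 7],
]

# OWAS action categories — rows: (back, arms) in sheet order; columns: legs 1-7,
# each load 1-3.
_OWAS_SHEET = [
    # legs:  1        2        3        4        5        6        7
    [1, 1, 1, 1, 1, 1, 1, 1, 1, 2, 2, 2, 2, 2, 2, 1, 1, 1, 1, 1, 1],   # back1 arms1
    [1, 1, 1, 1, 1, 1, 1, 1, 1, 2, 2, 2, 2, 2, 2, 1, 1, 1, 1, 1, 1],   # back1 arms2
    [1, 1, 1, 1, 1, 1, 1, 1, 2, 2, 2, 3, 2, 2, 2, 1, 1, 1, 1, 1, 2],   # back1 arms3
    [2, 2, 3, 2, 2, 3, 2, 2, 3, 3, 3, 3, 3, 3, 3, 2, 2, 2, 2, 3, 3],   # back2 arms1
    [2, 2, 3, 2, 2, 3, 2, 3, 3, 3, 4, 4, 3, 4, 4, 3, 3, 4, 2, 3, 4],   # back2 arms2
    [3, 3, 4, 2, 2, 3, 3, 3, 3, 3, 4, 4, 4, 4, 4, 4, 4, 4, 2, 3, 4],   # back2 arms3
    [1, 1, 1, 1, 1, 1, 1, 1, 2, 3, 3, 3, 4, 4, 4, 1, 1, 1, 1, 1, 1],   # back3 arms1
    [2, 2, 3, 1, 1, 1, 1, 1, 2, 4, 4, 4, 4, 4, 4, 3, 3, 3, 1, 1, 1],   # back3 arms2
    [2, 2, 3, 1, 1, 1, 2, 3, 3, 4, 4, 4, 4, 4, 4, 4, 4, 4, 1, 1, 1],   # back3 arms3
    [2, 3, 3, 2, 2, 3, 2, 2, 3, 4, 4, 4, 4, 4, 4, 4, 4, 4, 2, 3, 4],   # back4 arms1
    [3, 3, 4, 2, 3, 4, 3, 3, 4, 4, 4, 4, 4, 4, 4, 4, 4, 4, 2, 3, 4],   # back4 arms2
    [4, 4, 4, 2, 3, 4, 3, 3, 4, 4, 4, 4, 4, 4, 4, 4, 4, 4, 2, 3, 4],   # back4 arms3
]


def reba_table_a() -> np.ndarray:
    """(trunk, neck, legs) -> score, reshaped from the sheet layout."""
    sheet = np.array(_REBA_A_SHEET)          # (trunk, neck*legs)
    return sheet.reshape(5, 3, 4)


def reba_table_b() -> np.ndarray:
    """(upper_arm, lower_arm, wrist) -> score."""
    sheet = np.array(_REBA_B_SHEET)          # (ua, la*wrist)
    return sheet.reshape(6, 2, 3)


def reba_table_c() -> np.ndarray:
    return np.array(_REBA_C_SHEET)


def rula_table_a() -> np.ndarray:
    """(upper_arm, lower_arm, wrist, twist) -> score."""
    sheet = np.array(_RULA_A_SHEET)          # (ua*la, wrist*twist)
    return sheet.reshape(6, 3, 4, 2)


def rula_table_b() -> np.ndarray:
    """(neck, trunk, legs) -> score."""
    sheet = np.array(_RULA_B_SHEET)          # (neck, trunk*legs)
    return sheet.reshape(6, 6, 2)


def rula_table_c() -> np.ndarray:
    return np.array(_RULA_C_SHEET)


def owas_categories() -> np.ndarray:
    """(back, arms, legs, load) -> action category."""
    sheet = np.array(_OWAS_SHEET)            # (back*arms, legs*load)
    return sheet.reshape(4, 3, 7, 3)
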