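"""Bundled Q-matrices.

`sim_qc` is the 21-item, 5-attribute category-level Q-matrix used throughout
the simulation studies: items 1-13 have two sequential categories, items
14-16 have three, and items 17-21 are single-category (dichotomous), for 37
category rows in total.
"""

from __future__ import annotations

import io

from .qc import QcMatrix, read_qc_matrix

_SIM_QC_CSV = """\
item,cat,A1,A2,A3,A4,A5
1,1,1,0,0,0,0
1,2,0,1,0,0,0
2,1,0,0,1,0,0
2,2,0,0,0,1,0
3,1,0,0,0,0,1
3,2,1,0,0,0,0
4,1,0,0,0,0,1
4,2,0,0,0,1,0
5,1,0,0,1,0,0
5,2,0,1,0,0,0
6,1,1,0,0,0,0
6,2,0,1,1,0,0
7,1,0,0,1,0,0
7,2,0,0,0,1,1
8,1,0,0,0,0,1
8,2,1,1,0,0,0
9,1,0,0,0,1,1
9,2,0,0,1,0,0
10,1,0,1,0,1,0
10,2,1,0,0,0,0
11,1,1,1,0,0,0
11,2,0,0,0,0,1
12,1,1,1,1,0,0
12,2,0,0,0,1,1
13,1,1,1,0,0,0
13,2,0,0,1,1,1
14,1,1,0,1,0,0
14,2,0,0,0,1,0
14,3,0,0,0,0,1
15,1,0,0,0,0,1
15,2,0,0,1,1,0
15,3,0,1,0,0,0
16,1,1,0,0,0,0
16,2,0,1,0,0,0
16,3,0,0,1,1,0
17,1,1,0,0,0,0
18,1,0,1,0,0,0
19,1,0,0,1,0,0
20,1,0,0,0,1,0
21,1,0,0,0,0,1
"""


def sim_qc() -> QcMatrix:
    """The 21-item, K=5 simulation Q_c matrix (16 polytomous + 5 dichotomous items)."""
    return read_qc_matrix(io.StringIO(_SIM_QC_CSV))
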