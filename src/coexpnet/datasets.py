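"""Bundled reference tables.

``neighborhood_screen_reference`` returns the published per-gene PPI
neighborhood counts and Fisher statistics for 31 tumor-specific genes
from a cervical-cancer co-expression study (background: N = 17,381
protein-interaction network genes, of which K = 392 were co-expressed).
Columns ``a`` (co-expressed neighbors) and ``b`` (other neighbors) are
the inputs of the screen; ``ratio_printed`` and ``p_printed`` are the
values as printed at their original precision, kept as strings so that
reproduction tests can compare at exactly that precision.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["neighborhood_screen_reference", "REFERENCE_N", "REFERENCE_K"]

REFERENCE_N = 17_381
REFERENCE_K = 392

# gene, a (co-expressed neighbors), b (other neighbors), printed ratio, printed p
_ROWS = [
    ("CCNE1", 12, 87, "0.121212", "2.31E-06"),
    ("CDT1", 11, 60, "0.15493", "5.08E-07"),
    ("MCM6", 15, 108, "0.121951", "1.16E-07"),
    ("ORC6", 7, 26, "0.212121", "7.24E-06"),
    ("CDK1", 33, 203, "0.139831", "4.17E-17"),
    ("MCM10", 10, 55, "0.153846", "1.80E-06"),
    ("FOXM1", 13, 72, "0.152941", "5.45E-08"),
    ("DSN1", 8, 44, "0.153846", "1.97E-05"),
    ("CENPE", 7, 33, "0.175", "2.76E-05"),
    ("BUB1B", 16, 88, "0.153846", "1.44E-09"),
    ("CENPH", 8, 28, "0.222222", "1.08E-06"),
    ("NDC80", 16, 68, "0.190476", "5.22E-11"),
    ("RMI1", 6, 17, "0.26087", "9.24E-06"),
    ("CCNA2", 16, 119, "0.118519", "6.61E-08"),
    ("POLA1", 12, 42, "0.222222", "2.14E-09"),
    ("MCM3", 19, 160, "0.106145", "2.40E-08"),
    ("RAD51", 14, 112, "0.111111", "9.75E-07"),
    ("FBXO5", 9, 29, "0.236842", "1.26E-07"),
    ("CHEK1", 17, 99, "0.146552", "9.53E-10"),
    ("CENPA", 14, 102, "0.12069", "3.51E-07"),
    ("CDC7", 11, 24, "0.314286", "1.71E-10"),
    ("CENPN", 7, 19, "0.269231", "1.28E-06"),
    ("CCNE2", 7, 29, "0.194444", "1.34E-05"),
    ("E2F1", 16, 122, "0.115942", "9.02E-08"),
    ("PRC1", 11, 33, "0.25", "2.63E-09"),
    ("TIPIN", 5, 11, "0.3125", "2.02E-05"),
    ("CDC6", 18, 50, "0.264706", "7.03E-15"),
    ("NUF2", 10, 34, "0.227273", "3.80E-08"),
    ("CDC45", 10, 39, "0.204082", "1.14E-07"),
    ("DBF4", 8, 21, "0.275862", "1.77E-07"),
    ("CENPK", 7, 8, "0.466667", "1.55E-08"),
]


def neighborhood_screen_reference() -> pd.DataFrame:
    """Published neighborhood-screen rows as a DataFrame (see module docs)."""
    df = pd.DataFrame(_ROWS, columns=["gene", "a", "b", "ratio_printed", "p_printed"])
    df["K"] = REFERENCE_K
    df["N"] = REFERENCE_N
    return df
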