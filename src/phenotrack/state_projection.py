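"""Butterfly projection of per-cell state-signature scores.

Glioblastoma cells are commonly placed on a two-axis "butterfly" plot
built from four meta-module signature scores — neural-progenitor-like
(NPC), oligodendrocyte-progenitor-like (OPC), astrocyte-like (AC) and
mesenchymal-like (MES) — plus a cell-cycle score overlay. For each cell:

    D = max(OPC, NPC) - max(AC, MES)
    X = log2((OPC - NPC) + 1)   if D > 0
        log2((AC - MES) + 1)    if D < 0
    Y = sign(D) * log2(|D| + 1)
    CCS = G1/S score + G2/M score

``Y = log2(D + 1)`` is undefined for D <= -1, so the signed form above is
used: it agrees with the plain form for D >= 0 and mirrors it for D < 0,
keeping the sign of Y coherent with D. D = 0 maps to the origin.

Signature scoring itself (AUCell-style gene-set enrichment) is out of
scope: this module consumes a per-cell score table and emits coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError


@dataclass
class CellStateScores:
    """One cell's signature scores (dimensionless, finite reals)."""

    cell_id: str
    opc: float
    npc: float
    ac: float
    mes: float
    g1s: float = 0.0
    g2m: float = 0.0

    def __post_init__(self) -> None:
        vals = [self.opc, self.npc, self.ac, self.mes, self.g1s, self.g2m]
        if not all(np.isfinite(v) for v in vals):
            raise InputError(f"non-finite score for cell {self.cell_id!r}")


def butterfly_coords(s: CellStateScores) -> tuple[float, float, float]:
    """(X, Y, D) of one cell; raises on a non-positive log argument."""
    d = max(s.opc, s.npc) - max(s.ac, s.mes)
    if d == 0:
        return 0.0, 0.0, 0.0
    if d > 0:
        arg = (s.opc - s.npc) + 1.0
        pair = "OPC - NPC"
    else:
        arg = (s.ac - s.mes) + 1.0
        pair = "AC - MES"
    if arg <= 0:
        raise InputError(
            f"log2 argument ({pair} + 1) = {arg} <= 0 for cell {s.cell_id!r}"
        )
    x = float(np.log2(arg))
    y = float(np.sign(d) * np.log2(abs(d) + 1.0))
    return x, y, float(d)


def cell_cycle_score(s: CellStateScores) -> float:
    """CCS = G1/S score + G2/M score (proliferation proxy)."""
    return float(s.g1s + s.g2m)


_COLUMN_ALIASES = {
    "opc": ("opc", "opc_like", "opc-like"),
    "npc": ("npc", "npc_like", "npc-like"),
    "ac": ("ac", "ac_like", "ac-like"),
    "mes": ("mes", "mes_like", "mes-like"),
    "g1s": ("g1s", "g1_s", "g1/s"),
    "g2m": ("g2m", "g2_m", "g2/m"),
}


def project_table(scores: pd.DataFrame) -> pd.DataFrame:
    """Vectorized butterfly projection of a per-cell score table.

    Expects columns cell_id, opc, npc, ac, mes and optionally g1s, g2m
    (case-insensitive, "-like" suffixes tolerated). Returns cell_id, X,
    Y, D, CCS.
    """
    cols = {c.lower().strip(): c for c in scores.columns}

    def pick(key: str, required: bool = True) -> str | None:
        for alias in _COLUMN_ALIASES[key]:
            if alias in cols:
                return cols[alias]
        if required:
            raise InputError(f"scores table lacks a {key!r} column")
        return None

    id_col = cols.get("cell_id") or cols.get("cell") or scores.columns[0]
    rows = []
    g1s_col = pick("g1s", required=False)
    g2m_col = pick("g2m", required=False)
    for _, r in scores.iterrows():
        s = CellStateScores(
            cell_id=str(r[id_col]),
            opc=float(r[pick("opc")]), npc=float(r[pick("npc")]),
            ac=float(r[pick("ac")]), mes=float(r[pick("mes")]),
            g1s=float(r[g1s_col]) if g1s_col else 0.0,
            g2m=float(r[g2m_col]) if g2m_col else 0.0,
        )
        x, y, d = butterfly_coords(s)
        rows.append(
            dict(cell_id=s.cell_id, X=x, Y=y, D=d, CCS=cell_cycle_score(s))
        )
    return pd.DataFrame(rows, columns=["cell_id", "X", "Y", "D", "CCS"])
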