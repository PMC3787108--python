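"""Per-gene normalized dinucleotide content (XpY observed/expected ratio).

CpG O/E = P_CpG / (P_C * P_G), where P_CpG is the frequency of CpG
dinucleotides and P_C, P_G the mononucleotide frequencies. Values well
below 1 indicate CpG depletion — the mutational footprint of germline
cytosine methylation — so the statistic serves as a sequence-derived
methylation proxy. The same ratio is computed for any dinucleotide
(TpG and CpA matter for the deamination signature).

Counting conventions: overlapping windows, single strand, left to right.
P_XY is taken over valid windows (both bases unambiguous, about L-1 of
them) while P_X and P_Y are taken over valid bases (L); windows touching
a non-ACGT base are excluded from both the window count and the XY count,
and non-ACGT bases are excluded from the base counts. An all-over-L
variant is available for sensitivity checks via ``denominator="bases"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from cpgoe.seqio import GeneRecord

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}

# byte-level lookup: ACGT -> 0..3, anything else -> 4 (ambiguous)
_LUT = np.full(256, 4, dtype=np.uint8)
for _b, _c in _BASE_CODE.items():
    _LUT[ord(_b)] = _c


def encode(sequence: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes (A,C,G,T -> 0..3, other -> 4)."""
    raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    return _LUT[raw]


@dataclass(frozen=True)
class DinucStats:
    """Counts and O/E value for one dinucleotide in one gene.

    ``oe`` is NaN (undefined) when either mononucleotide is absent or no
    valid window exists.
    """

    gene_id: str
    dinucleotide: tuple[str, str]
    n_xy: int
    n_windows: int
    n_x: int
    n_y: int
    n_bases: int
    oe: float

    @property
    def defined(self) -> bool:
        return not math.isnan(self.oe)


def _parse_dinuc(dinucleotide: str | tuple[str, str]) -> tuple[str, str]:
    if isinstance(dinucleotide, str):
        pair = (dinucleotide[0], dinucleotide[1]) if len(dinucleotide) == 2 else None
    else:
        pair = tuple(dinucleotide)
    if pair is None or len(pair) != 2 or any(b not in _BASE_CODE for b in pair):
        raise ValueError(f"invalid dinucleotide {dinucleotide!r}")
    return pair  # type: ignore[return-value]


def compute_oe(
    sequence: str,
    dinucleotide: str | tuple[str, str] = "CG",
    gene_id: str = "",
    denominator: str = "windows",
) -> DinucStats:
    """Observed/expected ratio of one dinucleotide in one sequence.

    oe = (n_XY / n_windows) / ((n_X / n_bases) * (n_Y / n_bases)).
    With ``denominator="bases"`` the window frequency is divided by
    n_bases instead of n_windows.
    """
    x, y = _parse_dinuc(dinucleotide)
    if len(sequence) < 2:
        raise ValueError("sequence must be at least 2 nt for a dinucleotide count")
    codes = encode(sequence.upper())
    return _oe_from_codes(codes, x, y, gene_id, denominator)


def _oe_from_codes(
    codes: np.ndarray, x: str, y: str, gene_id: str, denominator: str = "windows"
) -> DinucStats:
    if denominator not in ("windows", "bases"):
        raise ValueError(f"unknown denominator convention {denominator!r}")
    cx, cy = _BASE_CODE[x], _BASE_CODE[y]
    valid = codes < 4
    n_bases = int(valid.sum())
    n_x = int((codes == cx).sum())
    n_y = int((codes == cy).sum())
    left, right = codes[:-1], codes[1:]
    window_ok = (left < 4) & (right < 4)
    n_windows = int(window_ok.sum())
    n_xy = int(((left == cx) & (right == cy)).sum())
    if n_x == 0 or n_y == 0 or n_windows == 0:
        oe = float("nan")
    else:
        denom = n_windows if denominator == "windows" else n_bases
        p_xy = n_xy / denom
        oe = p_xy / ((n_x / n_bases) * (n_y / n_bases))
    return DinucStats(
        gene_id=gene_id,
        dinucleotide=(x, y),
        n_xy=n_xy,
        n_windows=n_windows,
        n_x=n_x,
        n_y=n_y,
        n_bases=n_bases,
        oe=oe,
    )


def oe_table(
    records: Iterable[GeneRecord],
    dinucleotides: Sequence[str | tuple[str, str]] = ("CG",),
    denominator: str = "windows",
) -> pd.DataFrame:
    """Per-(gene, dinucleotide) O/E table.

    One row per combination; undefined O/E values appear as NaN in the
    ``oe`` column and should be excluded before mixture fitting.
    """
    pairs = [_parse_dinuc(d) for d in dinucleotides]
    rows = []
    for rec in records:
        codes = encode(rec.sequence)
        for x, y in pairs:
            st = _oe_from_codes(codes, x, y, rec.gene_id, denominator)
            rows.append(
                (
                    st.gene_id,
                    f"{x}p{y}",
                    st.n_xy,
                    st.n_windows,
                    st.n_x,
                    st.n_y,
                    st.n_bases,
                    st.oe,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "dinucleotide",
            "n_xy",
            "n_windows",
            "n_x",
            "n_y",
            "n_bases",
            "oe",
        ],
    )
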