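"""Synthetic coding-sequence datasets with a planted methylation signature.

Each gene belongs to a latent class — "methylated" (low CpG O/E) or
"unmethylated" (high) — drawn with the mixture weight w1; its target CpG
O/E is drawn from the class's normal component. A first-order Markov
chain is calibrated per target so that the generated sequence's long-run
CpG O/E equals the target while the stationary base composition stays at
the requested values. With deamination coupling on, the dinucleotide mass
removed from CpG is moved onto CpA and TpG — the mutational products of
methyl-cytosine deamination on the two strands — so CpG-depleted genes
show the right-shifted TpG/CpA distributions real methylated genomes do.

Calibration works on the joint dinucleotide distribution J (J[x, y] is
the stationary probability of observing x followed by y): the CpG cell
is pinned at oe * pi_C * pi_G, the coupling mass is seeded onto the CpA
and TpG cells, and Sinkhorn scaling restores both marginals to the base
composition exactly; an outer loop re-pins the CpG cell after each
Sinkhorn pass. The transition matrix T = J / pi then has stationary
distribution pi and P(G|C) = oe * pi_G by construction.

GO annotations are sampled per gene: background terms at class-independent
rates plus planted terms whose annotation rate differs between classes,
giving the enrichment stage a known ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from cpgoe import composition
from cpgoe.seqio import GeneRecord, write_fasta, write_annotation

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_A, _C, _G, _T = 0, 1, 2, 3

OE_CLIP = (0.05, 1.5)  # spans the empirical histogram range while staying feasible


def _load_presets() -> dict:
    with resources.files("cpgoe.data").joinpath("presets.json").open() as fh:
        return json.load(fh)


PRESETS = _load_presets()


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic dataset.

    ``mixture`` is (w1, mu1, sd1, mu2, sd2) for the target CpG O/E
    distribution — the low-mean component is the methylated class.
    ``planted_terms`` entries are (go_id, category, rate_low, rate_high):
    per-gene annotation probabilities by true class.
    """

    n_genes: int = 20_000
    seq_length: int = 999
    mixture: tuple[float, float, float, float, float] = (0.84, 0.39, 0.14, 0.81, 0.14)
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    deamination_coupling: bool = True
    n_go_terms: int = 50
    planted_terms: tuple[tuple[str, str, float, float], ...] = (
        ("GO:0009987", "BP", 0.40, 0.05),
        ("GO:0005576", "CC", 0.05, 0.40),
    )
    multi_isogroup_fraction: float = 0.0
    contamination_fraction: float = 0.0
    rng_seed: int = 0

    def __post_init__(self):
        w1, mu1, sd1, mu2, sd2 = self.mixture
        if not 0 < w1 < 1:
            raise ValueError("mixture weight w1 must be in (0, 1)")
        if sd1 <= 0 or sd2 <= 0:
            raise ValueError("mixture sds must be positive")
        if self.seq_length < 300:
            raise ValueError("seq_length must be >= 300 so default filters keep genes")
        pi = np.asarray(self.base_composition, dtype=float)
        if pi.shape != (4,) or abs(pi.sum() - 1.0) > 1e-9 or np.any(pi <= 0):
            raise ValueError("base_composition must be 4 positive values summing to 1")
        lo, hi = OE_CLIP
        if min(np.clip([mu1, mu2], lo, hi)) * pi[_G] >= 1.0:
            raise ValueError("mixture means infeasible after clipping")

    @classmethod
    def from_preset(cls, name: str, **overrides) -> "SimConfig":
        if name not in PRESETS:
            raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
        mx = PRESETS[name]["mixture"]
        mixture = (mx["w1"], mx["mu1"], mx["sd1"], mx["mu2"], mx["sd2"])
        return cls(mixture=mixture, **overrides)


def _sinkhorn(J: np.ndarray, pi: np.ndarray, n_iter: int = 200, tol: float = 1e-14) -> np.ndarray:
    J = J.copy()
    for _ in range(n_iter):
        J *= (pi / J.sum(axis=1))[:, None]
        J *= pi / J.sum(axis=0)
        if abs(J.sum(axis=1) - pi).max() < tol:
            break
    return J


def calibrate_transitions(
    target_oe: float,
    base_composition=(0.25, 0.25, 0.25, 0.25),
    coupling: bool = True,
) -> np.ndarray:
    """4x4 transition matrix (A,C,G,T order) realizing a target CpG O/E.

    The returned matrix is row-stochastic, has stationary distribution
    equal to ``base_composition`` and P(G|C) = target_oe * pi_G, so the
    long-run CpG O/E of the chain equals the target. With ``coupling``
    the dinucleotide mass removed from CpG is seeded onto the CpA and TpG
    cells (half each) before the marginals are restored, producing the
    deamination-like TpG/CpA excess in CpG-depleted sequences.
    """
    pi = np.asarray(base_composition, dtype=float)
    if target_oe <= 0 or target_oe >= 1.0 / pi[_G]:
        raise ValueError(
            f"target O/E must lie in (0, {1.0 / pi[_G]:.4g}) "
            f"(P(G|C) = oe * pi_G must stay below 1); got {target_oe}"
        )
    pinned = target_oe * pi[_C] * pi[_G]
    deficit = (1.0 - target_oe) * pi[_C] * pi[_G]

    seed = np.outer(pi, pi)
    seed[_C, _G] = pinned
    if coupling:
        seed[_C, _A] = max(seed[_C, _A] + deficit / 2.0, 1e-9)
        seed[_T, _G] = max(seed[_T, _G] + deficit / 2.0, 1e-9)
    else:
        non_g = [_A, _C, _T]
        seed[_C, non_g] += deficit * pi[non_g] / (1.0 - pi[_G])
        seed[_C, non_g] = np.maximum(seed[_C, non_g], 1e-9)

    J = seed
    for _ in range(100):
        J = _sinkhorn(J, pi)
        err = J[_C, _G] - pinned
        if abs(err) < 1e-13:
            break
        J[_C, _G] *= pinned / J[_C, _G]
    T = J / J.sum(axis=1, keepdims=True)
    return T


@lru_cache(maxsize=4096)
def _cached_matrix(
    target_key: int, base_composition: tuple, coupling: bool
) -> np.ndarray:
    # targets quantized to 1e-3 in O/E units upstream
    return calibrate_transitions(target_key / 1000.0, base_composition, coupling)


def _sample_chains(
    targets: np.ndarray,
    length: int,
    pi: np.ndarray,
    coupling: bool,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample one Markov-chain sequence per target O/E, vectorized over genes."""
    n = targets.size
    keys = np.round(targets * 1000).astype(int)
    pi_t = tuple(float(v) for v in pi)
    unique_keys = np.unique(keys)
    mats = {k: _cached_matrix(int(k), pi_t, coupling) for k in unique_keys}
    cum = np.empty((n, 4, 4))
    for k in unique_keys:
        cum[keys == k] = np.cumsum(mats[k], axis=1)

    seqs = np.empty((n, length), dtype=np.int8)
    state = np.searchsorted(np.cumsum(pi), rng.random(n), side="right").astype(np.int8)
    state = np.minimum(state, 3)
    seqs[:, 0] = state
    idx = np.arange(n)
    for pos in range(1, length):
        rows = cum[idx, state]  # (n, 4) cumulative transition rows
        u = rng.random(n)
        state = (u[:, None] >= rows).sum(axis=1).astype(np.int8)
        state = np.minimum(state, 3)
        seqs[:, pos] = state
    return seqs


def _decode(seq_codes: np.ndarray) -> str:
    return _BASES[seq_codes.astype(np.uint8)].tobytes().decode("ascii")


@dataclass(frozen=True)
class SimResult:
    records: list[GeneRecord]
    truth: pd.DataFrame  # gene_id, true_class, target_oe, realized_oe
    annotation: pd.DataFrame = field(repr=False)


def generate_dataset(cfg: SimConfig) -> SimResult:
    """Generate sequences, annotation and ground truth for one config.

    Fully reproducible from ``cfg.rng_seed``; the same config yields
    byte-identical outputs.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    w1, mu1, sd1, mu2, sd2 = cfg.mixture
    pi = np.asarray(cfg.base_composition, dtype=float)
    n = cfg.n_genes

    width = max(6, len(str(max(n, 1))))
    gene_ids = [f"g{i:0{width}d}" for i in range(n)]
    methylated = rng.random(n) < w1
    targets = np.where(
        methylated,
        rng.normal(mu1, sd1, size=n),
        rng.normal(mu2, sd2, size=n),
    )
    lo = max(OE_CLIP[0], 1e-3)
    hi = min(OE_CLIP[1], (1.0 / pi[_G]) - 1e-3)
    if lo >= hi:
        raise ValueError("infeasible target range after clipping")
    targets = np.clip(targets, lo, hi)

    if n > 0:
        seqs = _sample_chains(targets, cfg.seq_length, pi, cfg.deamination_coupling, rng)
    else:
        seqs = np.empty((0, cfg.seq_length), dtype=np.int8)

    # isogroups: optionally collapse a fraction of consecutive gene pairs
    isogroups = [f"iso{i:0{width}d}" for i in range(n)]
    if cfg.multi_isogroup_fraction > 0 and n > 1:
        n_pairs = int(cfg.multi_isogroup_fraction * n / 2)
        pair_first = rng.choice(n - 1, size=n_pairs, replace=False)
        for i in pair_first:
            isogroups[i + 1] = isogroups[i]

    taxa = np.where(
        rng.random(n) < cfg.contamination_fraction, "protist", "insect"
    )

    # GO annotation: background terms at class-independent rates, planted
    # terms at class-specific rates
    categories = ("BP", "CC", "MF")
    background = [
        (f"GO:{7000000 + i:07d}", categories[i % 3], float(r), float(r))
        for i, r in enumerate(rng.uniform(0.01, 0.10, size=cfg.n_go_terms))
    ]
    all_terms = list(cfg.planted_terms) + background
    go_sets: list[set[tuple[str, str]]] = [set() for _ in range(n)]
    for go_id, category, rate_low, rate_high in all_terms:
        rate = np.where(methylated, rate_low, rate_high)
        hit = rng.random(n) < rate
        for i in np.nonzero(hit)[0]:
            go_sets[i].add((go_id, category))

    records = []
    realized = np.empty(n)
    for i in range(n):
        seq = _decode(seqs[i])
        realized[i] = composition.compute_oe(seq, "CG", gene_id=gene_ids[i]).oe
        records.append(
            GeneRecord(
                gene_id=gene_ids[i],
                sequence=seq,
                isogroup_id=isogroups[i],
                taxon_label=str(taxa[i]),
                go_terms=frozenset(go_sets[i]),
            )
        )

    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "true_class": np.where(methylated, "methylated", "unmethylated"),
            "target_oe": targets,
            "realized_oe": realized,
        }
    )
    annotation = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "isogroup_id": isogroups,
            "taxon_label": taxa,
            "go_terms": [
                ";".join(f"{g}|{c}" for g, c in sorted(s)) for s in go_sets
            ],
        }
    )
    return SimResult(records=records, truth=truth, annotation=annotation)


def write_dataset(result: SimResult, outdir: str | Path) -> dict[str, Path]:
    """Write FASTA, annotation TSV and truth TSV for one generated dataset."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "sequences.fasta",
        "annotation": outdir / "annotation.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_fasta(result.records, paths["fasta"])
    write_annotation(result.records, paths["annotation"])
    result.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
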