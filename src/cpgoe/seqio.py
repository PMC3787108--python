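"""Sequence and annotation I/O, ORF extraction, and sequence-selection filters.

Coding sequences enter the dinucleotide analysis only after three filters:
a taxon filter (EST libraries from whole animals contain sequences from gut
symbionts and other non-host organisms), redundancy removal (one random
representative per isogroup, since isotigs of one isogroup are splice
variants of the same gene), and a minimum-length cutoff (short CDS give
noisy dinucleotide frequencies).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO

GO_CATEGORIES = frozenset({"BP", "CC", "MF"})

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

def _revcomp(seq: str) -> str:
    # standard complement; IUPAC ambiguity codes deliberately collapse to N
    comp = []
    for base in reversed(seq):
        if base == "A":
            comp.append("T")
        elif base == "C":
            comp.append("G")
        elif base == "G":
            comp.append("C")
        elif base == "T":
            comp.append("A")
        else:
            comp.append("N")
    return "".join(comp)


@dataclass(frozen=True)
class GeneRecord:
    """One coding sequence with optional annotation.

    ``isogroup_id`` is None for genes not assigned to any isogroup
    (assembly singletons); the dedup filter treats each such gene as its
    own group. ``go_terms`` is a frozenset of ``(go_id, category)`` pairs
    with category in {BP, CC, MF}.
    """

    gene_id: str
    sequence: str
    isogroup_id: str | None = None
    taxon_label: str | None = None
    go_terms: frozenset[tuple[str, str]] = field(default_factory=frozenset)

    def __post_init__(self):
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"{self.gene_id}: sequence must be non-empty")


@dataclass(frozen=True)
class FilterConfig:
    """Settings for the three sequence-selection filters.

    Defaults mirror the analysis conditions: discard CDS shorter than
    300 nt, keep only sequences whose top-hit taxon is labelled "insect",
    and keep one random representative per isogroup.
    """

    min_length: int = 300
    allowed_taxon_labels: frozenset[str] = frozenset({"insect"})
    dedup_per_group: bool = True
    rng_seed: int = 0

    def __post_init__(self):
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")


class FastaParseError(ValueError):
    pass


def read_fasta(path: str | Path) -> list[GeneRecord]:
    """Read a FASTA file into GeneRecords (id + uppercased sequence only).

    The token before the first whitespace of each header becomes the
    gene_id. Raises :class:`FastaParseError` for content before the first
    header (naming the line) or a duplicated gene_id.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FastaParseError(
                    f"{path}: line {lineno}: sequence data before first '>' header"
                )
            break
    records: list[GeneRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        gene_id = rec.id
        if gene_id in seen:
            raise FastaParseError(f"{path}: duplicate gene_id {gene_id!r}")
        seen.add(gene_id)
        records.append(GeneRecord(gene_id=gene_id, sequence=str(rec.seq).upper()))
    return records


def write_fasta(records: Iterable[GeneRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.gene_id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def _parse_go_field(text: str, gene_id: str) -> frozenset[tuple[str, str]]:
    terms = set()
    for token in text.split(";"):
        token = token.strip()
        if not token:
            continue
        try:
            go_id, category = token.split("|")
        except ValueError:
            raise ValueError(
                f"gene {gene_id!r}: malformed GO token {token!r} (expected GO:NNNNNNN|CAT)"
            ) from None
        if category not in GO_CATEGORIES:
            raise ValueError(
                f"gene {gene_id!r}: unknown GO category {category!r} in {token!r}"
            )
        terms.add((go_id, category))
    return frozenset(terms)


def read_annotation(path: str | Path) -> dict[str, tuple[str, str, frozenset[tuple[str, str]]]]:
    """Read the annotation TSV mapping gene_id -> (isogroup, taxon, GO terms).

    Expects header columns gene_id, isogroup_id, taxon_label, go_terms;
    go_terms is a semicolon-joined list of ``GO:NNNNNNN|CAT`` tokens and
    may be empty.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["gene_id", "isogroup_id", "taxon_label", "go_terms"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing annotation columns {missing}")
    dupes = df["gene_id"][df["gene_id"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"{path}: duplicate gene_id rows: {sorted(set(dupes))}")
    out = {}
    for row in df.itertuples(index=False):
        out[row.gene_id] = (
            row.isogroup_id or None,
            row.taxon_label or None,
            _parse_go_field(row.go_terms, row.gene_id),
        )
    return out


def write_annotation(records: Iterable[GeneRecord], path: str | Path) -> None:
    rows = []
    for rec in records:
        go = ";".join(
            f"{go_id}|{cat}" for go_id, cat in sorted(rec.go_terms)
        )
        rows.append(
            {
                "gene_id": rec.gene_id,
                "isogroup_id": rec.isogroup_id or "",
                "taxon_label": rec.taxon_label or "",
                "go_terms": go,
            }
        )
    pd.DataFrame(rows, columns=["gene_id", "isogroup_id", "taxon_label", "go_terms"]).to_csv(
        path, sep="\t", index=False
    )


def join_annotation(
    records: Iterable[GeneRecord],
    annotation: dict[str, tuple[str, str, frozenset[tuple[str, str]]]],
) -> list[GeneRecord]:
    """Attach isogroup/taxon/GO annotation onto sequence records.

    Genes absent from the annotation table stay annotation-less (None
    isogroup and taxon, empty GO set).
    """
    joined = []
    for rec in records:
        if rec.gene_id in annotation:
            isogroup, taxon, go = annotation[rec.gene_id]
            joined.append(
                replace(rec, isogroup_id=isogroup, taxon_label=taxon, go_terms=go)
            )
        else:
            joined.append(rec)
    return joined


def _frames(sequence: str) -> list[str]:
    """The six reading frames in canonical order +1,+2,+3,-1,-2,-3."""
    rc = _revcomp(sequence)
    return [sequence, sequence[1:], sequence[2:], rc, rc[1:], rc[2:]]


def _longest_orf_in_frame(frame: str) -> tuple[int, str | None]:
    """Longest ATG..stop ORF (stop included) within one frame; (-1, None) if none."""
    codons = [frame[i : i + 3] for i in range(0, len(frame) - 2, 3)]
    best_start, best_len = -1, -1
    start = None
    for i, codon in enumerate(codons):
        if start is None and codon == "ATG":
            start = i
        elif start is not None and codon in STOP_CODONS:
            length = (i - start + 1) * 3
            if length > best_len:
                best_start, best_len = start, length
            start = None
    if best_len < 0:
        return -1, None
    return best_start * 3, frame[best_start * 3 : best_start * 3 + best_len]


def _longest_stop_free_in_frame(frame: str) -> tuple[int, str]:
    """Longest codon-aligned run free of stop codons within one frame."""
    n_codons = (len(frame)) // 3
    best_start, best_len = 0, 0
    run_start = 0
    for i in range(n_codons + 1):
        codon = frame[i * 3 : i * 3 + 3] if i < n_codons else None
        if codon is None or codon in STOP_CODONS:
            run_len = i - run_start
            if run_len > best_len:
                best_start, best_len = run_start, run_len
            run_start = i + 1
    return best_start * 3, frame[best_start * 3 : (best_start + best_len) * 3]


def extract_longest_orf(sequence: str) -> str | None:
    """Longest ATG-initiated, stop-terminated ORF over all six frames.

    The stop codon is included. If no complete ORF exists in any frame,
    falls back to the longest codon-aligned stop-free stretch. Ties go to
    the earlier frame in the order +1,+2,+3,-1,-2,-3, then leftmost.
    Returns None for sequences shorter than 3 nt.
    """
    if len(sequence) < 3:
        return None
    sequence = sequence.upper()
    best: str | None = None
    for frame in _frames(sequence):
        pos, orf = _longest_orf_in_frame(frame)
        if orf is not None and (best is None or len(orf) > len(best)):
            best = orf
    if best is not None:
        return best
    for frame in _frames(sequence):
        _, run = _longest_stop_free_in_frame(frame)
        if best is None or len(run) > len(best):
            best = run
    return best if best else None


def _group_key(rec: GeneRecord) -> str:
    # singletons get a synthetic per-gene group so dedup never drops them
    if rec.isogroup_id is None:
        return f"__singleton__{rec.gene_id}"
    return rec.isogroup_id


def filter_report(
    records: list[GeneRecord], cfg: FilterConfig
) -> tuple[list[GeneRecord], pd.DataFrame]:
    """Apply the three filters and report a per-gene kept/dropped log.

    Application order is taxon -> isogroup dedup -> length. The isogroup
    representative is a uniform draw over the group's members sorted by
    gene_id, seeded per (rng_seed, isogroup), so the choice is independent
    of input order and stable across runs. Output is sorted by gene_id.
    """
    log_rows: list[dict] = []
    surviving: list[GeneRecord] = []
    for rec in records:
        if rec.taxon_label not in cfg.allowed_taxon_labels:
            log_rows.append(
                {"gene_id": rec.gene_id, "kept": False, "reason": "taxon"}
            )
        else:
            surviving.append(rec)

    if cfg.dedup_per_group:
        groups: dict[str, list[GeneRecord]] = {}
        for rec in surviving:
            groups.setdefault(_group_key(rec), []).append(rec)
        surviving = []
        for key, members in groups.items():
            members = sorted(members, key=lambda r: r.gene_id)
            pick = random.Random(f"{cfg.rng_seed}:{key}").randrange(len(members))
            for i, rec in enumerate(members):
                if i == pick:
                    surviving.append(rec)
                else:
                    log_rows.append(
                        {
                            "gene_id": rec.gene_id,
                            "kept": False,
                            "reason": "isogroup_dedup",
                        }
                    )

    kept: list[GeneRecord] = []
    for rec in surviving:
        if len(rec.sequence) < cfg.min_length:
            log_rows.append(
                {"gene_id": rec.gene_id, "kept": False, "reason": "length"}
            )
        else:
            kept.append(rec)
            log_rows.append({"gene_id": rec.gene_id, "kept": True, "reason": ""})

    kept.sort(key=lambda r: r.gene_id)
    log = pd.DataFrame(log_rows, columns=["gene_id", "kept", "reason"]).sort_values(
        "gene_id", kind="stable", ignore_index=True
    )
    return kept, log


def apply_filters(records: list[GeneRecord], cfg: FilterConfig) -> list[GeneRecord]:
    """Taxon, isogroup-dedup and length filters; see :func:`filter_report`."""
    kept, _ = filter_report(records, cfg)
    return kept
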