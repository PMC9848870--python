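"""Codon extraction, start/stop tabulation and RSCU.

Relative synonymous codon usage of codon ``c`` in a synonymous family ``F``
is ``count(c) * |F| / sum(count(c') for c' in F)``; 1 means no bias.  The
genetic code defaults to the vertebrate mitochondrial code (NCBI table 2),
under which AGA/AGG are stops, ATA joins Met and TGA joins Trp — so every
amino-acid family has at least two members.  Incomplete stop codons (a
trailing T or TA completed by polyadenylation) are recognized and excluded
from codon counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd
from Bio.Data import CodonTable

from .annotation_io import Feature, GenomeRecord, extract_feature_sequence

_BASES = "TCAG"
ALL_CODONS = tuple(a + b + c for a in _BASES for b in _BASES for c in _BASES)


def genetic_code(table_id: int = 2) -> dict[str, str]:
    """codon (DNA) -> one-letter amino acid; stops map to '*'."""
    tab = CodonTable.unambiguous_dna_by_id[table_id]
    code = dict(tab.forward_table)
    for stop in tab.stop_codons:
        code[stop] = "*"
    return code


def synonymous_families(table_id: int = 2) -> dict[str, tuple[str, ...]]:
    """amino acid -> codons of its family (stops excluded)."""
    code = genetic_code(table_id)
    fams: dict[str, list[str]] = {}
    for codon in ALL_CODONS:
        aa = code[codon]
        if aa != "*":
            fams.setdefault(aa, []).append(codon)
    return {aa: tuple(sorted(cs)) for aa, cs in fams.items()}


def to_rna(codon: str) -> str:
    return codon.replace("T", "U")


@dataclass
class CodonExtraction:
    codons: list[str]
    start: str
    stop: str | None
    complete: bool
    internal_stops: list[int] = field(default_factory=list)


def extract_codons(rec: GenomeRecord, pcg: Feature,
                   table_id: int = 2) -> CodonExtraction:
    """Codon list, start and stop codon, and completeness for one PCG.

    The trailing 3-mer is the stop if it is a stop codon of the code; else a
    trailing 1-2-mer "T"/"TA" is an incomplete stop.  The codon list excludes
    the stop in either case.  Internal stops are reported as a warning
    (possible mis-annotation), never silently dropped.
    """
    stops = set(CodonTable.unambiguous_dna_by_id[table_id].stop_codons)
    seq = extract_feature_sequence(rec, pcg)[pcg.reading_offset or 0:]
    rem = len(seq) % 3
    stop: str | None = None
    complete = True
    if rem == 0 and len(seq) >= 3 and seq[-3:] in stops:
        stop = seq[-3:]
        seq = seq[:-3]
    elif rem in (1, 2) and seq[-rem:] in ("T", "TA"):
        stop = seq[-rem:]
        complete = False
        seq = seq[:-rem]
    else:
        if rem:
            seq = seq[:-rem]
        complete = False
    codons = [seq[i:i + 3] for i in range(0, len(seq), 3)]
    internal = [i for i, c in enumerate(codons[1:], start=1) if c in stops]
    if internal:
        warnings.warn(
            f"{rec.identifier}:{pcg.canonical_name}: internal stop codon(s) "
            f"at codon position(s) {internal}")
    return CodonExtraction(codons, codons[0] if codons else "", stop,
                           complete, internal)


@dataclass
class CodonCountTable:
    """Counts over all 64 codons (DNA keys) under one genetic code."""

    counts: dict[str, int]
    n_incomplete_stops: int = 0
    table_id: int = 2

    @classmethod
    def empty(cls, table_id: int = 2) -> "CodonCountTable":
        return cls({c: 0 for c in ALL_CODONS}, 0, table_id)

    def add(self, extraction: CodonExtraction) -> None:
        for c in extraction.codons:
            if c in self.counts:
                self.counts[c] += 1
        if extraction.stop is not None and not extraction.complete:
            self.n_incomplete_stops += 1

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def count_codons(records: list[GenomeRecord],
                 table_id: int = 2) -> CodonCountTable:
    """Pooled codon counts over all PCGs of all records."""
    table = CodonCountTable.empty(table_id)
    for rec in records:
        for pcg in rec.features_of_kind("PCG"):
            table.add(extract_codons(rec, pcg, table_id))
    return table


def rscu(counts: CodonCountTable) -> pd.DataFrame:
    """RSCU per codon, long form: amino_acid, codon (RNA), count, rscu.

    Within each nonzero family of size k the RSCU values sum to k; a family
    with zero total has undefined (NaN) RSCU.  Stop codons are excluded.
    """
    rows = []
    for aa, fam in sorted(synonymous_families(counts.table_id).items()):
        total = sum(counts.counts[c] for c in fam)
        for codon in fam:
            n = counts.counts[codon]
            rows.append({
                "amino_acid": aa, "codon": to_rna(codon), "count": n,
                "rscu": (n * len(fam) / total) if total else float("nan"),
            })
    return pd.DataFrame(rows)


def most_frequent_codons(rscu_table: pd.DataFrame, k: int = 1) -> list[str]:
    """Top-k codons by RSCU; ties by raw count, then alphabetically."""
    if k < 1:
        raise ValueError("k must be >= 1")
    df = rscu_table.dropna(subset=["rscu"])
    df = df.sort_values(["rscu", "count", "codon"],
                        ascending=[False, False, True], kind="mergesort")
    return df["codon"].head(k).tolist()


def start_stop_table(records: list[GenomeRecord],
                     table_id: int = 2) -> pd.DataFrame:
    """Start/stop codon matrix: one row per PCG x record."""
    rows = []
    for rec in records:
        for pcg in sorted(rec.features_of_kind("PCG"), key=lambda f: f.start):
            ex = extract_codons(rec, pcg, table_id)
            rows.append({
                "record": rec.identifier, "gene": pcg.canonical_name,
                "start": ex.start, "stop": ex.stop or "",
                "complete": ex.complete,
            })
    return pd.DataFrame(rows)


def rscu_long_table(records: list[GenomeRecord],
                    table_id: int = 2) -> pd.DataFrame:
    """Per-record RSCU long table suitable for stacked-bar plotting."""
    frames = []
    for rec in records:
        t = rscu(count_codons([rec], table_id))
        t.insert(0, "record", rec.identifier)
        frames.append(t)
    return pd.concat(frames, ignore_index=True)
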