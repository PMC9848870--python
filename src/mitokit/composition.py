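"""Base composition and strand-skew statistics for sequence partitions.

AT-skew = (A - T)/(A + T) and GC-skew = (G - C)/(G + C); both are undefined
(reported as None/NaN) when the denominator is zero.  Percentages use the
unambiguous-base denominator (A+C+G+T) by default; ambiguity codes are
excluded from all numerators and denominators so the skew bounds stay exact.
Codon-position statistics are computed in gene orientation (reading frame),
not genome strand.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import pandas as pd

from .annotation_io import Feature, GenomeRecord, extract_feature_sequence

#: Vertebrate mitochondrial stop codons (DNA alphabet).
MITO_STOPS = frozenset({"TAA", "TAG", "AGA", "AGG"})


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero, the convention of printed tables."""
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return x
    factor = 10 ** ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


@dataclass
class CompositionSummary:
    """Base counts and derived A+T%, AT-skew, GC-skew for one partition."""

    a: int
    c: int
    g: int
    t: int
    n_ambiguous: int
    length: int

    @property
    def pct_at(self) -> float | None:
        d = self.a + self.c + self.g + self.t
        return 100.0 * (self.a + self.t) / d if d else None

    @property
    def pct_gc(self) -> float | None:
        d = self.a + self.c + self.g + self.t
        return 100.0 * (self.g + self.c) / d if d else None

    def pct(self, base: str) -> float | None:
        d = self.a + self.c + self.g + self.t
        return 100.0 * getattr(self, base.lower()) / d if d else None

    @property
    def at_skew(self) -> float | None:
        d = self.a + self.t
        return (self.a - self.t) / d if d else None

    @property
    def gc_skew(self) -> float | None:
        d = self.g + self.c
        return (self.g - self.c) / d if d else None


def base_composition(seq: str) -> CompositionSummary:
    """Count bases case-insensitively; non-ACGT symbols count as ambiguous."""
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper().replace("U", "T")
    a, c, g, t = s.count("A"), s.count("C"), s.count("G"), s.count("T")
    gaps = s.count("-") + s.count(".")
    n_amb = len(s) - a - c - g - t - gaps
    return CompositionSummary(a, c, g, t, n_amb, len(s) - gaps)


def codon_position_split(
    rec: GenomeRecord, pcg_features: list[Feature] | None = None,
    drop_stop: bool = True,
) -> tuple[str, str, str]:
    """Split PCG coding sequence into the three codon-position streams.

    Per gene: the gene-orientation sequence is taken, ``reading_offset``
    leading bases are dropped, the trailing partial codon is dropped, and a
    complete stop codon is dropped when ``drop_stop``.  Streams are
    concatenated across genes in genome order.
    """
    if pcg_features is None:
        pcg_features = rec.features_of_kind("PCG")
    streams = ["", "", ""]
    for f in sorted(pcg_features, key=lambda f: f.start):
        seq = extract_feature_sequence(rec, f)[f.reading_offset or 0:]
        seq = seq[: len(seq) - len(seq) % 3]
        if drop_stop and len(seq) >= 3 and seq[-3:] in MITO_STOPS:
            seq = seq[:-3]
        if len(seq) < 3:
            warnings.warn(f"{f.canonical_name}: shorter than one codon "
                          "after trimming; skipped")
            continue
        for p in range(3):
            streams[p] += seq[p::3]
    return tuple(streams)


@dataclass
class PartitionSpec:
    """A named selection of sequence from each record.

    ``names``/``kinds`` select features (both None = whole genome);
    ``codon_positions`` restricts PCG sequence to a subset of {1,2,3};
    ``orientation`` 'gene' takes reading-strand sequence, 'genome' the
    J-strand slice; ``drop_stop_codons`` removes complete stop codons
    (the convention for "PCGs excluding stop codons").
    """

    name: str
    names: list[str] | None = None
    kinds: list[str] | None = None
    codon_positions: list[int] | None = None
    orientation: str = "gene"
    drop_stop_codons: bool = False

    def __post_init__(self) -> None:
        if self.codon_positions and self.kinds != ["PCG"] and self.names:
            pass  # explicit PCG names with codon positions are fine
        if self.codon_positions and not set(self.codon_positions) <= {1, 2, 3}:
            raise ValueError("codon_positions must be within {1,2,3}")

    def select(self, rec: GenomeRecord) -> str:
        if self.names is None and self.kinds is None:
            return rec.sequence
        feats = [
            f for f in sorted(rec.features, key=lambda f: f.start)
            if (self.names is None or f.canonical_name in self.names)
            and (self.kinds is None or f.kind in self.kinds)
        ]
        if not feats:
            return ""
        if self.codon_positions:
            s1, s2, s3 = codon_position_split(rec, feats)
            return "".join((s1, s2, s3)[p - 1] for p in sorted(self.codon_positions))
        if self.drop_stop_codons:
            s1, s2, s3 = codon_position_split(rec, feats)
            # reassemble codons from the three streams
            return "".join(a + b + c for a, b, c in zip(s1, s2, s3))
        if self.orientation == "genome":
            return "".join(rec.sequence[s:e] for f in feats for s, e in f.intervals)
        return "".join(extract_feature_sequence(rec, f) for f in feats)


#: Partitions mirroring the per-dataset layout of comparative mitogenome tables.
DEFAULT_PARTITIONS = [
    PartitionSpec("whole_genome"),
    PartitionSpec("PCGs", kinds=["PCG"], drop_stop_codons=True),
    PartitionSpec("codon_pos1", kinds=["PCG"], codon_positions=[1]),
    PartitionSpec("codon_pos2", kinds=["PCG"], codon_positions=[2]),
    PartitionSpec("codon_pos3", kinds=["PCG"], codon_positions=[3]),
    PartitionSpec("tRNAs", kinds=["tRNA"]),
    PartitionSpec("rrnS", names=["rrnS"]),
    PartitionSpec("rrnL", names=["rrnL"]),
    PartitionSpec("CR", names=["CR"]),
]


def partition_summary(
    records: list[GenomeRecord],
    spec: PartitionSpec,
    ndigits: int = 1,
) -> pd.DataFrame:
    """One composition row per record plus a cross-record mean row.

    Percent and skew fields are rounded half-up to ``ndigits`` decimals for
    reporting (skews to 3); counts stay exact.  A record in which the
    partition selects nothing yields a missing row, and the mean is taken
    over present rows.
    """
    rows = []
    for rec in records:
        seq = spec.select(rec)
        if not seq:
            rows.append({"record": rec.identifier, "partition": spec.name,
                         "length": pd.NA})
            continue
        comp = base_composition(seq)
        rows.append({
            "record": rec.identifier, "partition": spec.name,
            "length": comp.length,
            "pct_T": comp.pct("t"), "pct_C": comp.pct("c"),
            "pct_A": comp.pct("a"), "pct_G": comp.pct("g"),
            "pct_AT": comp.pct_at,
            "at_skew": comp.at_skew, "gc_skew": comp.gc_skew,
        })
    df = pd.DataFrame(rows)
    present = df.dropna(subset=["length"]) if "length" in df else df
    if len(present):
        mean_row = {"record": "mean", "partition": spec.name}
        for col in ("length", "pct_T", "pct_C", "pct_A", "pct_G", "pct_AT",
                    "at_skew", "gc_skew"):
            if col in present:
                mean_row[col] = present[col].astype(float).mean()
        df = pd.concat([df, pd.DataFrame([mean_row])], ignore_index=True)
    for col in ("pct_T", "pct_C", "pct_A", "pct_G", "pct_AT"):
        if col in df:
            df[col] = df[col].map(lambda v: round_half_up(v, ndigits)
                                  if pd.notna(v) else v)
    for col in ("at_skew", "gc_skew"):
        if col in df:
            df[col] = df[col].map(lambda v: round_half_up(v, 3)
                                  if pd.notna(v) else v)
    return df


def summarize(records: list[GenomeRecord],
              partitions: list[PartitionSpec] | None = None) -> pd.DataFrame:
    """Stacked partition summaries for a set of records."""
    partitions = partitions or DEFAULT_PARTITIONS
    return pd.concat(
        [partition_summary(records, p) for p in partitions], ignore_index=True
    )
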