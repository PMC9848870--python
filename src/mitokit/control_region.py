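"""Control-region (D-loop) analysis.

The avian CR divides into three domains: the extended termination-associated
sequence (ETAS) domain I, the central conserved domain II carrying the F, E,
D, C, B and bird-similarity boxes, and the conserved-sequence-block domain
III carrying CSB1.  Domain boundaries are configuration (explicit coordinates
or anchor motifs — they are not derivable from sequence alone), conserved-box
consensi are editable pattern data, and tandem repeats are detected by
seed-and-extend over all unit lengths.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import pandas as pd

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


# ---------------------------------------------------------------------------
# Alignment variability


def variable_site_proportion(alignment, interval: tuple[int, int] | None = None,
                             denominator: str = "comparable") -> float:
    """Percent of variable columns in a gapped alignment.

    A column is variable iff it contains >= 2 distinct non-gap residues.
    ``denominator`` 'comparable' divides by columns with >= 2 non-gap
    residues (default); 'all' divides by every column in the interval.
    """
    seqs = list(alignment.values()) if isinstance(alignment, dict) else list(alignment)
    if len(seqs) < 2:
        raise ValueError("need at least two aligned sequences")
    ncol = len(seqs[0])
    if any(len(s) != ncol for s in seqs):
        raise ValueError("aligned sequences must have equal length")
    lo, hi = interval if interval else (0, ncol)
    variable = comparable = 0
    for j in range(lo, hi):
        residues = [s[j].upper() for s in seqs if s[j] not in "-."]
        if len(residues) >= 2:
            comparable += 1
            if len(set(residues)) >= 2:
                variable += 1
    denom = comparable if denominator == "comparable" else hi - lo
    if denom == 0:
        raise ValueError("no comparable columns in interval")
    return 100.0 * variable / denom


# ---------------------------------------------------------------------------
# Motif search (IUPAC-aware Hamming)


@dataclass
class MotifHit:
    name: str
    start: int
    end: int
    mismatches: int
    matched: str


def _mismatches(window: str, pattern: str) -> int:
    mm = 0
    for b, p in zip(window, pattern):
        if b.upper() not in IUPAC.get(p.upper(), ""):
            mm += 1
    return mm


def find_motif(seq: str, pattern: str, max_mismatch: int = 0,
               name: str = "motif") -> list[MotifHit]:
    """All occurrences of an IUPAC pattern within ``max_mismatch`` Hamming
    mismatches; overlapping hits allowed; sorted by (mismatches, start)."""
    if not pattern:
        raise ValueError("empty pattern")
    m = len(pattern)
    hits = []
    for i in range(len(seq) - m + 1):
        window = seq[i:i + m]
        mm = _mismatches(window, pattern)
        if mm <= max_mismatch:
            hits.append(MotifHit(name, i, i + m, mm, window))
    hits.sort(key=lambda h: (h.mismatches, h.start))
    return hits


def load_motif_config(path=None) -> list[tuple[str, str, int]]:
    """(name, pattern, max_mismatch) rows; default = packaged avian CR set."""
    if path is None:
        ref = importlib.resources.files("mitokit.data") / "cr_motifs.tsv"
        text = ref.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, pattern, mm = line.split("\t")
        rows.append((name, pattern, int(mm)))
    return rows


def scan_motifs(seq: str, config=None) -> pd.DataFrame:
    """Best-per-motif scan of a CR sequence against a motif configuration."""
    config = config if config is not None else load_motif_config()
    rows = []
    for name, pattern, mm in config:
        hits = find_motif(seq, pattern, mm, name)
        if hits:
            best = hits[0]
            rows.append({"motif": name, "found": True, "start": best.start,
                         "end": best.end, "mismatches": best.mismatches,
                         "matched": best.matched})
        else:
            rows.append({"motif": name, "found": False, "start": -1,
                         "end": -1, "mismatches": -1, "matched": ""})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Domain partition


@dataclass
class DomainPartition:
    """ETAS domain I, central domain II, CSB domain III in CR-local
    0-based half-open coordinates."""

    domain_i: tuple[int, int]
    domain_ii: tuple[int, int]
    domain_iii: tuple[int, int]

    def __post_init__(self) -> None:
        ivals = [self.domain_i, self.domain_ii, self.domain_iii]
        for (s, e) in ivals:
            if s >= e:
                raise ValueError(f"empty or inverted domain interval ({s},{e})")
        if not (self.domain_i[1] <= self.domain_ii[0]
                and self.domain_ii[1] <= self.domain_iii[0]):
            raise ValueError("domain intervals must be ordered and disjoint")

    def as_dict(self) -> dict[str, tuple[int, int]]:
        return {"I": self.domain_i, "II": self.domain_ii,
                "III": self.domain_iii}


def partition_cr(cr_seq: str, boundaries: tuple[int, int, int, int] | None = None,
                 anchors: bool = False, config=None) -> DomainPartition:
    """Partition a CR into its three domains.

    Explicit mode: ``boundaries`` = (start_I, start_II, start_III, end).
    Anchor mode (``anchors=True``): domain II begins at the best F-box hit
    and domain III at the best CSB1 hit from the motif configuration; an
    absent anchor is an error.
    """
    if anchors:
        config = config if config is not None else load_motif_config()
        by_name = {name: (pat, mm) for name, pat, mm in config}
        starts = {}
        for anchor in ("F_box", "CSB1"):
            if anchor not in by_name:
                raise ValueError(f"anchor motif {anchor!r} missing from config")
            pat, mm = by_name[anchor]
            hits = find_motif(cr_seq, pat, mm, anchor)
            if not hits:
                raise ValueError(f"anchor motif {anchor!r} not found in CR")
            starts[anchor] = hits[0].start
        boundaries = (0, starts["F_box"], starts["CSB1"], len(cr_seq))
    if boundaries is None:
        raise ValueError("supply explicit boundaries or anchors=True")
    a, b, c, d = boundaries
    return DomainPartition((a, b), (b, c), (c, d))


def domain_variability(alignment, partition: DomainPartition,
                       denominator: str = "comparable") -> dict[str, float]:
    """Variable-site percentage per CR domain (alignment-column space)."""
    return {dom: variable_site_proportion(alignment, iv, denominator)
            for dom, iv in partition.as_dict().items()}


# ---------------------------------------------------------------------------
# Tandem repeats


@dataclass
class TandemRepeat:
    unit: str
    unit_length: int
    copies: float
    start: int
    end: int
    purity: float


def _pure_runs(seq: str, unit: int):
    """Maximal intervals [s, e) with seq[i] == seq[i+unit] for all
    i in [s, e-unit); yields (s, e)."""
    n = len(seq)
    i = 0
    while i < n - unit:
        if seq[i] == seq[i + unit]:
            j = i
            while j < n - unit and seq[j] == seq[j + unit]:
                j += 1
            yield i, j + unit
            i = j + 1
        else:
            i += 1


#: Minimum total span (bp) for a repeat to be reported in CR summaries;
#: suppresses the 2-copy micro-repeats every random sequence contains.
REPORTABLE_SPAN = 24


def find_tandem_repeats(seq: str, min_unit: int = 2, max_unit: int = 200,
                        min_copies: float = 2.0, min_purity: float = 0.9,
                        min_length: int = 1) -> list[TandemRepeat]:
    """Detect tandem repeats by match-at-lag runs over all unit lengths.

    For each unit length u, maximal runs of positions matching the position
    u bases ahead define candidate loci; a locus of extent [s, e) has
    (e-s)/u copies (fractional allowed).  With ``min_purity`` < 1 pure runs
    separated by few mismatches are merged while the fraction of matching
    positions stays >= min_purity.  ``min_length`` filters by total span
    (summaries use :data:`REPORTABLE_SPAN` to ignore micro-repeats).
    Reports of the same locus at a multiple of a smaller reported unit are
    collapsed to the smallest unit.  Hits are sorted by (start, unit_length).
    """
    n = len(seq)
    if min_unit < 1 or max_unit < min_unit:
        raise ValueError("require 1 <= min_unit <= max_unit")
    max_unit = min(max_unit, n // 2)
    candidates: list[TandemRepeat] = []
    for u in range(min_unit, max_unit + 1):
        runs = list(_pure_runs(seq, u))
        # greedy extension: merge consecutive pure runs while the fraction
        # of lag-matching positions in the merged span stays >= min_purity
        merged: list[tuple[int, int, int]] = []  # (s, e, matched positions)
        for s, e in runs:
            if min_purity < 1.0 and merged:
                ps, pe, pmatched = merged[-1]
                total = e - ps - u
                matched = pmatched + (e - s - u)
                if total > 0 and matched / total >= min_purity:
                    merged[-1] = (ps, e, matched)
                    continue
            merged.append((s, e, e - s - u))
        for s, e, matched in merged:
            total = e - s - u
            purity = matched / total if total > 0 else 1.0
            copies = (e - s) / u
            if copies >= min_copies and purity >= min_purity \
                    and e - s >= min_length:
                candidates.append(TandemRepeat(seq[s:s + u], u, copies, s, e,
                                               purity))
    # collapse nested reports: drop a hit whose span is covered by a kept hit
    # with a smaller unit
    candidates.sort(key=lambda r: (r.unit_length, r.start))
    kept: list[TandemRepeat] = []
    for cand in candidates:
        covered = any(k.start <= cand.start and cand.end <= k.end
                      and k.unit_length < cand.unit_length for k in kept)
        if not covered:
            kept.append(cand)
    kept.sort(key=lambda r: (r.start, r.unit_length))
    return kept
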