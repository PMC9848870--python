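"""Circular gene orders, breakpoint comparison, and intergenic spacers.

A gene order is the circular, strand-aware list of canonical gene tokens in
J-strand 5'->3' genome coordinates, rotated to a canonical anchor (trnF by
default, the start of conventional avian numbering).  Breakpoint distance
counts circular adjacencies present in one order but not the other, with
(x -> y) on given strands equivalent to (y -> x) with both strands flipped —
the rearrangement-literature convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .annotation_io import GenomeRecord, STANDARD_TOKENS

#: Canonical passerine mitogenome order (J-strand 5'->3' from trnF), with the
#: avian cob-trnT-trnP-nad6-trnE-CR block before trnF.
CANONICAL_PASSERINE_ORDER: tuple[tuple[str, str], ...] = (
    ("trnF", "J"), ("rrnS", "J"), ("trnV", "J"), ("rrnL", "J"),
    ("trnL(uur)", "J"), ("nad1", "J"), ("trnI", "J"), ("trnQ", "N"),
    ("trnM", "J"), ("nad2", "J"), ("trnW", "J"), ("trnA", "N"),
    ("trnN", "N"), ("trnC", "N"), ("trnY", "N"), ("cox1", "J"),
    ("trnS(ucn)", "N"), ("trnD", "J"), ("cox2", "J"), ("trnK", "J"),
    ("atp8", "J"), ("atp6", "J"), ("cox3", "J"), ("trnG", "J"),
    ("nad3", "J"), ("trnR", "J"), ("nad4l", "J"), ("nad4", "J"),
    ("trnH", "J"), ("trnS(agy)", "J"), ("trnL(cun)", "J"), ("nad5", "J"),
    ("cob", "J"), ("trnT", "J"), ("trnP", "N"), ("nad6", "N"),
    ("trnE", "N"), ("CR", "J"),
)


@dataclass(frozen=True)
class GeneOrderString:
    """Rotation-normalized circular list of (canonical_name, strand)."""

    order: tuple[tuple[str, str], ...]
    anchor: str = "trnF"

    @classmethod
    def from_pairs(cls, pairs, anchor: str = "trnF") -> "GeneOrderString":
        pairs = tuple((n, s) for n, s in pairs)
        names = [n for n, _ in pairs]
        dupes = sorted({n for n in names if names.count(n) > 1})
        if dupes:
            raise ValueError(f"duplicate gene tokens: {dupes}")
        if anchor in names:
            i = names.index(anchor)
            pairs = pairs[i:] + pairs[:i]
        else:
            # no anchor: normalize to the lexicographically minimal rotation
            rots = [pairs[i:] + pairs[:i] for i in range(len(pairs))]
            pairs = min(rots)
        return cls(pairs, anchor)

    def __str__(self) -> str:
        return "-".join(("-" if s == "N" else "") + n for n, s in self.order)

    def missing_standard_tokens(self) -> list[str]:
        present = {n for n, _ in self.order}
        return [t for t in STANDARD_TOKENS if t not in present]

    def adjacencies(self) -> set:
        """Circular strand-aware adjacency set (orientation-normalized)."""
        adjs = set()
        n = len(self.order)
        for i in range(n):
            x, y = self.order[i], self.order[(i + 1) % n]
            fwd = (x, y)
            rev = ((y[0], _flip(y[1])), (x[0], _flip(x[1])))
            adjs.add(min(fwd, rev))
        return adjs


def _flip(strand: str) -> str:
    return "N" if strand == "J" else "J"


def extract_gene_order(rec: GenomeRecord, anchor: str = "trnF") -> GeneOrderString:
    """Gene order from feature coordinates (origin-spanning features are
    placed by their 5' end); file order of features is irrelevant."""
    feats = sorted(rec.features, key=lambda f: f.intervals[0][0])
    go = GeneOrderString.from_pairs(
        [(f.canonical_name, f.strand) for f in feats], anchor)
    missing = go.missing_standard_tokens()
    if missing:
        warnings.warn(f"{rec.identifier}: missing standard genes: {missing}")
    return go


def compare_orders(a: GeneOrderString, b: GeneOrderString) -> dict:
    """Breakpoints = adjacencies of ``a`` absent from ``b`` (circular,
    strand-aware).  Tokens not shared by both orders are dropped pairwise
    with a warning before comparison."""
    ta = {n for n, _ in a.order}
    tb = {n for n, _ in b.order}
    shared = ta & tb
    if ta != tb:
        warnings.warn(f"token universes differ; dropping {sorted(ta ^ tb)}")
        a = GeneOrderString.from_pairs(
            [p for p in a.order if p[0] in shared], a.anchor)
        b = GeneOrderString.from_pairs(
            [p for p in b.order if p[0] in shared], b.anchor)
    adj_a, adj_b = a.adjacencies(), b.adjacencies()
    breakpoints = len(adj_a - adj_b)
    diffs = sorted(
        f"{x[0]}({x[1]})->{y[0]}({y[1]})" for x, y in adj_a - adj_b)
    return {"identical": breakpoints == 0, "breakpoints": breakpoints,
            "differing_segments": diffs}


def _circular_arc(f, genome_length: int) -> tuple[int, int]:
    """Genomic extent of a feature as a circular arc [start, end), where
    end may exceed the genome length for an origin-spanning feature."""
    ivals = sorted(f.intervals)
    spans_origin = (len(ivals) > 1 and ivals[0][0] == 0
                    and ivals[-1][1] == genome_length)
    if spans_origin:
        return ivals[-1][0], ivals[0][1] + genome_length
    return ivals[0][0], ivals[-1][1]


def spacer_table(rec: GenomeRecord) -> pd.DataFrame:
    """Gaps/overlaps between adjacent features on the circular genome.

    gap = downstream.start - upstream.end; negative = overlap; zero =
    abutting.  The pair spanning the origin is included for circular
    records.
    """
    if len(rec.features) < 2:
        raise ValueError("need at least two features")
    arcs = sorted(
        ((_circular_arc(f, rec.length), f) for f in rec.features),
        key=lambda t: t[0])
    rows = []
    n = len(arcs)
    last = n if rec.circular else n - 1
    for i in range(last):
        (s_up, e_up), up = arcs[i]
        (s_dn, e_dn), down = arcs[(i + 1) % n]
        if i == n - 1:  # wraparound pair
            gap = s_dn + rec.length - e_up
        else:
            gap = s_dn - e_up
        rows.append({"upstream": up.canonical_name,
                     "downstream": down.canonical_name, "gap": int(gap)})
    return pd.DataFrame(rows)


def spacer_summary(rec: GenomeRecord) -> dict:
    """Spacer statistics as printed in mitogenome descriptions: only gaps
    >= 1 bp count as intergenic spacers; overlaps are summarized separately."""
    table = spacer_table(rec)
    gaps = table[table["gap"] >= 1]
    overlaps = table[table["gap"] < 0]
    out = {
        "n_spacers": int(len(gaps)),
        "min_spacer": int(gaps["gap"].min()) if len(gaps) else 0,
        "max_spacer": int(gaps["gap"].max()) if len(gaps) else 0,
        "total_spacer_bp": int(gaps["gap"].sum()) if len(gaps) else 0,
        "n_overlaps": int(len(overlaps)),
    }
    if len(gaps):
        top = gaps.loc[gaps["gap"].idxmax()]
        out["longest_spacer_between"] = (top["upstream"], top["downstream"])
    return out
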