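"""Desk-scale phylogenetics: concatenation, distances, NJ, tree queries.

This stage consumes pre-computed per-gene alignments, builds a partitioned
supermatrix, computes p or Kimura two-parameter (K2P) distances with
pairwise deletion, and runs neighbor joining with a deterministic
lexicographic tie-break.  Heavy model-based inference is delegated to
external tools through PHYLIP/NEXUS export; dendropy provides the tree
container, Newick I/O and bipartition machinery for topology checks.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

GAPS = set("-.?")
VALID = set("ACGT")
TRANSITIONS = {frozenset("AG"), frozenset("CT")}


@dataclass
class Supermatrix:
    """Concatenated gapped alignment with a gene -> column-interval map."""

    taxa: list[str]
    sequences: dict[str, str]
    partitions: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError("unequal row lengths in supermatrix")

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.sequences.values()))) if self.sequences else 0


def concatenate(per_gene_alignments: dict[str, dict[str, str]],
                taxa: list[str] | None = None) -> Supermatrix:
    """Concatenate per-gene alignments; a taxon missing from a gene gets a
    gap-filled block.  Duplicate taxa within a gene are an error (guaranteed
    by dict input); taxa appearing in alignments but not in ``taxa`` are an
    error."""
    if taxa is None:
        seen: list[str] = []
        for aln in per_gene_alignments.values():
            for t in aln:
                if t not in seen:
                    seen.append(t)
        taxa = seen
    seqs = {t: [] for t in taxa}
    partitions = {}
    col = 0
    for gene, aln in per_gene_alignments.items():
        unknown = set(aln) - set(taxa)
        if unknown:
            raise ValueError(f"{gene}: taxa not in taxon list: {sorted(unknown)}")
        width = {len(s) for s in aln.values()}
        if len(width) > 1:
            raise ValueError(f"{gene}: ragged alignment")
        w = width.pop() if width else 0
        for t in taxa:
            seqs[t].append(aln.get(t, "-" * w).upper())
        partitions[gene] = (col, col + w)
        col += w
    return Supermatrix(list(taxa), {t: "".join(p) for t, p in seqs.items()},
                       partitions)


# ---------------------------------------------------------------------------
# Distances


def pairwise_distance(s1: str, s2: str, model: str = "p") -> float:
    """p or K2P distance with pairwise deletion of gap/ambiguous sites.

    K2P: d = -1/2 ln(1-2P-Q) - 1/4 ln(1-2Q) with P, Q the transition and
    transversion proportions among valid sites.
    """
    valid = diffs = ts = 0
    for a, b in zip(s1.upper(), s2.upper()):
        if a in VALID and b in VALID:
            valid += 1
            if a != b:
                diffs += 1
                if frozenset((a, b)) in TRANSITIONS:
                    ts += 1
    if valid == 0:
        return float("nan")
    if model == "p":
        return diffs / valid
    if model in ("K2P", "k2p"):
        P = ts / valid
        Q = (diffs - ts) / valid
        w1, w2 = 1 - 2 * P - Q, 1 - 2 * Q
        if w1 <= 0 or w2 <= 0:
            return float("nan")
        return -0.5 * math.log(w1) - 0.25 * math.log(w2)
    raise ValueError(f"unknown model {model!r}")


def distance_matrix(sm: Supermatrix | dict[str, str],
                    model: str = "p") -> pd.DataFrame:
    seqs = sm.sequences if isinstance(sm, Supermatrix) else sm
    taxa = list(sm.taxa) if isinstance(sm, Supermatrix) else list(seqs)
    if len(taxa) < 2:
        raise ValueError("need at least two taxa")
    d = pd.DataFrame(0.0, index=taxa, columns=taxa)
    for i, a in enumerate(taxa):
        for b in taxa[i + 1:]:
            v = pairwise_distance(seqs[a], seqs[b], model)
            d.loc[a, b] = d.loc[b, a] = v
    return d


# ---------------------------------------------------------------------------
# Neighbor joining


def neighbor_joining(d: pd.DataFrame) -> dendropy.Tree:
    """Standard NJ with deterministic tie-breaking.

    When several pairs minimize the Q criterion, the lexicographically
    smallest (sorted) label pair is joined.  Negative branch lengths are
    clamped to zero with a warning.  Undefined distances are an error.
    """
    if d.isna().any().any():
        raise ValueError("distance matrix contains undefined entries")
    labels = list(d.index)
    if len(labels) < 3:
        raise ValueError("need at least three taxa")
    dist = {a: {b: float(d.loc[a, b]) for b in labels} for a in labels}
    newick_of = {t: t for t in labels}
    active = sorted(labels)
    clamped = False
    counter = 0
    while len(active) > 3:
        n = len(active)
        r = {a: sum(dist[a][b] for b in active if b != a) for a in active}
        best = None
        for i, a in enumerate(active):
            for b in active[i + 1:]:
                q = (n - 2) * dist[a][b] - r[a] - r[b]
                key = (q, *sorted((a, b)))
                if best is None or key < best:
                    best = key
                    pair = (a, b)
        a, b = pair
        la = 0.5 * dist[a][b] + (r[a] - r[b]) / (2 * (n - 2))
        lb = dist[a][b] - la
        if la < 0 or lb < 0:
            clamped = True
        la, lb = max(la, 0.0), max(lb, 0.0)
        node = f"__nj{counter}"
        counter += 1
        dist[node] = {}
        for c in active:
            if c in (a, b):
                continue
            dc = 0.5 * (dist[a][c] + dist[b][c] - dist[a][b])
            dist[node][c] = dist[c][node] = dc
        newick_of[node] = f"({newick_of[a]}:{la:.10g},{newick_of[b]}:{lb:.10g})"
        active = sorted([c for c in active if c not in (a, b)] + [node])
    a, b, c = active
    la = 0.5 * (dist[a][b] + dist[a][c] - dist[b][c])
    lb = 0.5 * (dist[a][b] + dist[b][c] - dist[a][c])
    lc = 0.5 * (dist[a][c] + dist[b][c] - dist[a][b])
    if min(la, lb, lc) < 0:
        clamped = True
    la, lb, lc = (max(x, 0.0) for x in (la, lb, lc))
    if clamped:
        warnings.warn("negative NJ branch length(s) clamped to 0")
    newick = (f"({newick_of[a]}:{la:.10g},{newick_of[b]}:{lb:.10g},"
              f"{newick_of[c]}:{lc:.10g});")
    return dendropy.Tree.get(data=newick, schema="newick")


# ---------------------------------------------------------------------------
# Tree queries


def _require_taxa(tree: dendropy.Tree, names) -> None:
    present = {lf.taxon.label for lf in tree.leaf_node_iter()}
    unknown = set(names) - present
    if unknown:
        raise ValueError(f"taxa not in tree: {sorted(unknown)}")


def is_monophyletic(tree: dendropy.Tree, taxa, outgroup: str) -> bool:
    """Root at ``outgroup``; true iff ``taxa`` form a complete clade."""
    taxa = set(taxa)
    _require_taxa(tree, taxa | {outgroup})
    t = tree.clone(depth=1)
    og = t.find_node_with_taxon_label(outgroup)
    t.reroot_at_edge(og.edge, update_bipartitions=False)
    mrca = t.mrca(taxon_labels=list(taxa))
    clade = {lf.taxon.label for lf in mrca.leaf_iter()}
    return clade == taxa


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Unrooted Robinson-Foulds (symmetric bipartition difference)."""
    tns = dendropy.TaxonNamespace()
    a = dendropy.Tree.get(data=t1.as_string(schema="newick"),
                          schema="newick", taxon_namespace=tns)
    b = dendropy.Tree.get(data=t2.as_string(schema="newick"),
                          schema="newick", taxon_namespace=tns)
    for t in (a, b):  # compare as unrooted topologies
        t.is_rooted = False
        t.collapse_basal_bifurcation()
        t.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(a, b)


def topology_matches(tree: dendropy.Tree, pattern_newick: str) -> bool:
    """True iff the tree, restricted to the pattern's taxa, displays every
    bipartition of the pattern (branch lengths and rotations ignored)."""
    tns = dendropy.TaxonNamespace()
    pat = dendropy.Tree.get(data=pattern_newick, schema="newick",
                            taxon_namespace=tns)
    pat_taxa = {lf.taxon.label for lf in pat.leaf_node_iter()}
    _require_taxa(tree, pat_taxa)
    sub = dendropy.Tree.get(data=tree.as_string(schema="newick"),
                            schema="newick", taxon_namespace=tns)
    sub.retain_taxa_with_labels(sorted(pat_taxa))
    pat.encode_bipartitions()
    sub.encode_bipartitions()
    pat_bips = {b.split_bitmask for b in pat.bipartition_encoding}
    sub_bips = {b.split_bitmask for b in sub.bipartition_encoding}
    return pat_bips <= sub_bips


# ---------------------------------------------------------------------------
# Export


def _sanitize_names(taxa: list[str]) -> dict[str, str]:
    mapping = {}
    for t in taxa:
        clean = re.sub(r"\s+", "_", t.strip())
        base = clean
        k = 2
        while clean in mapping.values():
            clean = f"{base}_{k}"
            k += 1
        mapping[t] = clean
    return mapping


def export_supermatrix(sm: Supermatrix, path, fmt: str = "phylip") -> dict[str, str]:
    """Write relaxed PHYLIP or NEXUS (with charsets); returns the taxon-name
    sanitization mapping (whitespace -> underscores)."""
    mapping = _sanitize_names(sm.taxa)
    with open(path, "w") as fh:
        if fmt == "phylip":
            fh.write(f"{len(sm.taxa)} {sm.n_columns}\n")
            for t in sm.taxa:
                fh.write(f"{mapping[t]}  {sm.sequences[t]}\n")
        elif fmt == "nexus":
            fh.write("#NEXUS\nBEGIN DATA;\n")
            fh.write(f"  DIMENSIONS NTAX={len(sm.taxa)} "
                     f"NCHAR={sm.n_columns};\n")
            fh.write("  FORMAT DATATYPE=DNA MISSING=? GAP=-;\n  MATRIX\n")
            for t in sm.taxa:
                fh.write(f"    {mapping[t]}  {sm.sequences[t]}\n")
            fh.write("  ;\nEND;\n\nBEGIN SETS;\n")
            for gene, (s, e) in sm.partitions.items():
                fh.write(f"  CHARSET {gene} = {s + 1}-{e};\n")
            fh.write("END;\n")
        else:
            raise ValueError(f"unknown format {fmt!r}")
    return mapping


def read_supermatrix(path, fmt: str = "phylip") -> Supermatrix:
    """Read back an exported supermatrix (partitions only from NEXUS)."""
    if fmt == "phylip":
        with open(path) as fh:
            header = fh.readline().split()
            ntax, ncol = int(header[0]), int(header[1])
            seqs = {}
            for line in fh:
                if not line.strip():
                    continue
                name, seq = line.split(None, 1)
                seqs[name] = seq.strip()
        if len(seqs) != ntax or any(len(s) != ncol for s in seqs.values()):
            raise ValueError("PHYLIP header does not match matrix")
        return Supermatrix(list(seqs), seqs, {"all": (0, ncol)})
    if fmt == "nexus":
        dm = dendropy.DnaCharacterMatrix.get(path=str(path), schema="nexus")
        seqs = {t.label.replace(" ", "_"): str(dm[t]).replace("?", "-")
                for t in dm.taxon_namespace}
        partitions = {}
        with open(path) as fh:
            for m in re.finditer(r"CHARSET\s+(\S+)\s*=\s*(\d+)-(\d+);",
                                 fh.read(), re.I):
                partitions[m.group(1)] = (int(m.group(2)) - 1, int(m.group(3)))
        if not partitions:
            partitions = {"all": (0, len(next(iter(seqs.values()))))}
        return Supermatrix(list(seqs), seqs, partitions)
    raise ValueError(f"unknown format {fmt!r}")
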