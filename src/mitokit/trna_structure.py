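"""Template-based tRNA cloverleaf folding.

A mitochondrial tRNA (66-75 nt in wagtails) is decomposed onto the cloverleaf
template by exhaustive search over arm-length combinations:

    acceptor stem (7 bp) - spacer - [D stem (0-4 bp) + D loop + D stem'] -
    spacer - anticodon stem (5 bp) + anticodon loop + stem' - variable loop -
    T stem (4-5 bp) + T loop + stem' - acceptor stem' (7) - 3' tail

Each candidate layout is scored pair-by-pair: Watson-Crick +2, G-U wobble
+1, mismatch -1.  Mismatched pairs (C-C, A-A, U-U and the like, observed in
real mitochondrial tRNAs) are allowed at a penalty rather than forbidden.
The D arm is called present when the D stem keeps >= 2 pairs; metazoan
mitochondrial trnS(agy) characteristically folds without one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

WC_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
WOBBLE_PAIRS = {("G", "U"), ("U", "G")}

PAIR_SCORE_WC = 2
PAIR_SCORE_WOBBLE = 1
PAIR_SCORE_MISMATCH = -1

#: Search windows over layout segment lengths (canonical value first in docs:
#: spacer1 2, D stem 4 / loop 8, spacer2 1, anticodon loop 7, variable 4,
#: T stem 5 / loop 7, tail 1).
DEFAULT_WINDOWS = {
    "spacer1": range(1, 4),
    "d_stem": range(0, 5),
    "d_loop": range(3, 12),
    "spacer2": range(0, 3),
    "ac_stem": (5,),
    "ac_loop": range(7, 10),
    "var_loop": range(3, 10),
    "t_stem": (4, 5),
    "t_loop": range(3, 10),
    "tail": range(0, 5),
}

ACCEPTOR_PAIRS = 7


def pair_score(b1: str, b2: str) -> int:
    if (b1, b2) in WC_PAIRS:
        return PAIR_SCORE_WC
    if (b1, b2) in WOBBLE_PAIRS:
        return PAIR_SCORE_WOBBLE
    return PAIR_SCORE_MISMATCH


@dataclass
class Arm:
    name: str
    stem5: tuple[int, int]  # half-open positions of the 5' stem strand
    stem3: tuple[int, int]
    loop: tuple[int, int] | None
    pairs: list[tuple[int, int]] = field(default_factory=list)
    mismatches: list[tuple[int, str, str]] = field(default_factory=list)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


@dataclass
class CloverleafFold:
    sequence: str  # RNA alphabet
    score: int
    arms: dict[str, Arm]
    anticodon_position: tuple[int, int] | None
    layout: dict[str, int]

    @property
    def dhu_present(self) -> bool:
        return self.arms["D"].n_pairs >= 2

    @property
    def mismatch_list(self) -> list[tuple[str, int, str, str]]:
        out = []
        for arm_name in ("acceptor", "D", "anticodon", "T"):
            for pos, b1, b2 in self.arms[arm_name].mismatches:
                out.append((arm_name, pos, b1, b2))
        return out

    def dot_bracket(self) -> str:
        marks = ["."] * len(self.sequence)
        for arm in self.arms.values():
            for i, j in arm.pairs:
                marks[i], marks[j] = "(", ")"
        return "".join(marks)


class NoCloverleafError(ValueError):
    pass


def _score_stem(seq: str, s5: tuple[int, int], s3: tuple[int, int]):
    """Score pairing of the 5' stem strand against the reversed 3' strand."""
    a, b = s5
    c, d = s3
    pairs, mism, total = [], [], 0
    n = b - a
    for k in range(n):
        i, j = a + k, d - 1 - k
        sc = pair_score(seq[i], seq[j])
        total += sc
        pairs.append((i, j))
        if sc == PAIR_SCORE_MISMATCH:
            mism.append((k, seq[i], seq[j]))
    return total, pairs, mism


def _layouts(length: int, windows: dict):
    keys = ("spacer1", "d_stem", "d_loop", "spacer2", "ac_loop",
            "var_loop", "t_stem", "t_loop")
    ac_stem = windows["ac_stem"][0]
    tails = set(windows["tail"])
    for combo in product(*(windows[k] for k in keys)):
        sp1, d, dl, sp2, al, vl, t, tl = combo
        used = (2 * ACCEPTOR_PAIRS + sp1 + 2 * d + dl + sp2
                + 2 * ac_stem + al + vl + 2 * t + tl)
        tail = length - used
        if tail in tails:
            yield {"spacer1": sp1, "d_stem": d, "d_loop": dl, "spacer2": sp2,
                   "ac_stem": ac_stem, "ac_loop": al, "var_loop": vl,
                   "t_stem": t, "t_loop": tl, "tail": tail}


def _canonical_penalty(lay: dict[str, int]) -> int:
    return (abs(lay["t_stem"] - 5) + abs(lay["ac_loop"] - 7)
            + abs(lay["t_loop"] - 7) + abs(lay["d_loop"] - 8)
            + abs(lay["spacer1"] - 2) + abs(lay["spacer2"] - 1)
            + abs(lay["var_loop"] - 4) + abs(lay["tail"] - 1))


def fold_cloverleaf(seq: str, anticodon: str | None = None,
                    windows: dict | None = None,
                    min_score: int = 20) -> CloverleafFold:
    """Best cloverleaf decomposition of a tRNA sequence.

    Exhaustive search over the layout windows; ties broken toward a larger
    D stem, then toward canonical arm lengths.  When ``anticodon`` is given
    the anticodon loop must contain it with >= 2 flanking loop bases on the
    5' side and >= 2 on the 3' side (canonical placement in a 7-nt loop).
    Raises :class:`NoCloverleafError` if no layout reaches ``min_score``.
    """
    rna = seq.upper().replace("T", "U")
    ac = anticodon.upper().replace("T", "U") if anticodon else None
    if not (55 <= len(rna) <= 100):
        raise ValueError(f"sequence length {len(rna)} outside [55, 100]")
    windows = windows or DEFAULT_WINDOWS
    score_of = {}
    for x in "ACGU":
        for y in "ACGU":
            score_of[x, y] = pair_score(x, y)
    best_lay = None
    best_key = None
    for lay in _layouts(len(rna), windows):
        segs = _segments(lay)
        if ac is not None and _anticodon_offset(rna, segs["ac_loop"], ac) is None:
            continue
        score = 0
        for s5, s3 in ((segs["acc5"], segs["acc3"]), (segs["d5"], segs["d3"]),
                       (segs["a5"], segs["a3"]), (segs["t5"], segs["t3"])):
            a, b = s5
            _, d = s3
            for k in range(b - a):
                score += score_of[rna[a + k], rna[d - 1 - k]]
        key = (score, lay["d_stem"], -_canonical_penalty(lay))
        if best_key is None or key > best_key:
            best_key = key
            best_lay = lay
    if best_lay is None or best_key[0] < min_score:
        raise NoCloverleafError(
            "no cloverleaf: best score "
            f"{'-inf' if best_lay is None else best_key[0]} < {min_score}")
    segs = _segments(best_lay)
    arms = {}
    score = 0
    for name, s5, s3, loop in (
        ("acceptor", segs["acc5"], segs["acc3"], None),
        ("D", segs["d5"], segs["d3"], segs["d_loop"]),
        ("anticodon", segs["a5"], segs["a3"], segs["ac_loop"]),
        ("T", segs["t5"], segs["t3"], segs["t_loop"]),
    ):
        sc, pairs, mism = _score_stem(rna, s5, s3)
        score += sc
        arms[name] = Arm(name, s5, s3, loop, pairs, mism)
    ac_pos = None
    if ac is not None:
        o = _anticodon_offset(rna, segs["ac_loop"], ac)
        ac_pos = (o, o + 3)
    return CloverleafFold(rna, score, arms, ac_pos, best_lay)


def _segments(lay: dict[str, int]) -> dict[str, tuple[int, int]]:
    p = 0
    segs = {}

    def take(name: str, n: int):
        nonlocal p
        segs[name] = (p, p + n)
        p += n

    take("acc5", ACCEPTOR_PAIRS)
    take("spacer1", lay["spacer1"])
    take("d5", lay["d_stem"])
    take("d_loop", lay["d_loop"])
    take("d3", lay["d_stem"])
    take("spacer2", lay["spacer2"])
    take("a5", lay["ac_stem"])
    take("ac_loop", lay["ac_loop"])
    take("a3", lay["ac_stem"])
    take("var_loop", lay["var_loop"])
    take("t5", lay["t_stem"])
    take("t_loop", lay["t_loop"])
    take("t3", lay["t_stem"])
    take("acc3", ACCEPTOR_PAIRS)
    take("tail", lay["tail"])
    return segs


def _anticodon_offset(rna: str, loop: tuple[int, int], ac: str) -> int | None:
    """Leftmost anticodon placement with >= 2 loop bases on each side."""
    lo, hi = loop
    for o in range(lo + 2, hi - 4):
        if rna[o:o + 3] == ac:
            return o
    return None


def fold_table(records, table_id: int = 2):
    """Per record x tRNA: arm sizes, score, DHU presence, mismatch count."""
    import pandas as pd

    from .annotation_io import extract_feature_sequence

    rows = []
    for rec in records:
        for f in sorted(rec.features_of_kind("tRNA"), key=lambda f: f.start):
            seq = extract_feature_sequence(rec, f)
            try:
                fold = fold_cloverleaf(seq, f.anticodon)
                rows.append({
                    "record": rec.identifier, "trna": f.canonical_name,
                    "length": len(seq), "score": fold.score,
                    "acceptor_pairs": fold.arms["acceptor"].n_pairs,
                    "d_pairs": fold.arms["D"].n_pairs,
                    "anticodon_pairs": fold.arms["anticodon"].n_pairs,
                    "t_pairs": fold.arms["T"].n_pairs,
                    "dhu_present": fold.dhu_present,
                    "n_mismatches": len(fold.mismatch_list),
                    "dot_bracket": fold.dot_bracket(),
                })
            except (NoCloverleafError, ValueError) as exc:
                rows.append({"record": rec.identifier,
                             "trna": f.canonical_name, "length": len(seq),
                             "score": None, "error": str(exc)})
    return pd.DataFrame(rows)
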