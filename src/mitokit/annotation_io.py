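"""Read/write annotated mitogenome records and normalize annotations.

The internal model uses 0-based half-open coordinates throughout; GenBank's
1-based inclusive convention is converted at the I/O boundary (Biopython
already presents locations half-open).  Strands are called ``J`` (major) and
``N`` (minor), following the mitochondrial literature.  A feature spanning the
circular origin is represented as two intervals ordered 5'->3' in gene
orientation.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

# Controlled vocabulary: 13 PCGs, 22 tRNAs, 2 rRNAs, control region.
PCG_NAMES = (
    "nad1", "nad2", "nad3", "nad4", "nad4l", "nad5", "nad6",
    "cox1", "cox2", "cox3", "atp6", "atp8", "cob",
)
TRNA_NAMES = (
    "trnF", "trnV", "trnL(uur)", "trnI", "trnQ", "trnM", "trnW", "trnA",
    "trnN", "trnC", "trnY", "trnS(ucn)", "trnD", "trnK", "trnG", "trnR",
    "trnH", "trnS(agy)", "trnL(cun)", "trnT", "trnP", "trnE",
)
RRNA_NAMES = ("rrnS", "rrnL")
ALL_GENE_NAMES = PCG_NAMES + TRNA_NAMES + RRNA_NAMES
STANDARD_TOKENS = ALL_GENE_NAMES + ("CR",)

#: Anticodons (DNA alphabet) of the 22 vertebrate mitochondrial tRNAs.
TRNA_ANTICODONS = {
    "trnF": "GAA", "trnV": "TAC", "trnL(uur)": "TAA", "trnI": "GAT",
    "trnQ": "TTG", "trnM": "CAT", "trnW": "TCA", "trnA": "TGC",
    "trnN": "GTT", "trnC": "GCA", "trnY": "GTA", "trnS(ucn)": "TGA",
    "trnD": "GTC", "trnK": "TTT", "trnG": "TCC", "trnR": "TCG",
    "trnH": "GTG", "trnS(agy)": "GCT", "trnL(cun)": "TAG", "trnT": "TGT",
    "trnP": "TGG", "trnE": "TTC",
}
_ANTICODON_TO_TRNA = {v: k for k, v in TRNA_ANTICODONS.items()}

_AA3_TO_TRNA = {
    "PHE": "trnF", "VAL": "trnV", "ILE": "trnI", "GLN": "trnQ",
    "MET": "trnM", "TRP": "trnW", "ALA": "trnA", "ASN": "trnN",
    "CYS": "trnC", "TYR": "trnY", "ASP": "trnD", "LYS": "trnK",
    "GLY": "trnG", "ARG": "trnR", "HIS": "trnH", "THR": "trnT",
    "PRO": "trnP", "GLU": "trnE",
}

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVNacgtryswkmbdhvn",
    "TGCAYRSWMKVHDBNtgcayrswmkvhdbn",
)


def reverse_complement(seq: str) -> str:
    """Reverse complement preserving IUPAC ambiguity codes."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Feature:
    """One annotated feature on a mitogenome.

    ``intervals`` are (start, end) pairs in 0-based half-open genome
    coordinates, ordered 5'->3' in gene orientation; an origin-spanning
    feature carries two intervals.
    """

    canonical_name: str
    kind: str  # PCG | tRNA | rRNA | CR | other
    strand: str = "J"  # J = major strand, N = minor strand
    intervals: list[tuple[int, int]] = field(default_factory=list)
    reading_offset: int | None = None  # from codon_start; PCGs only
    anticodon: str | None = None
    raw_label: str | None = None

    @property
    def start(self) -> int:
        return self.intervals[0][0]

    @property
    def end(self) -> int:
        return self.intervals[-1][1]

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.intervals)


@dataclass
class GenomeRecord:
    """An annotated (possibly circular) mitogenome."""

    identifier: str
    sequence: str
    circular: bool = True
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"{self.identifier}: empty sequence")
        n = len(self.sequence)
        for f in self.features:
            for s, e in f.intervals:
                if not (0 <= s < e <= n):
                    raise ValueError(
                        f"{self.identifier}:{f.canonical_name}: interval "
                        f"({s},{e}) outside [0,{n})"
                    )
        if sum(1 for f in self.features if f.kind == "CR") > 1:
            raise ValueError(f"{self.identifier}: more than one control region")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def get(self, canonical_name: str) -> Feature | None:
        for f in self.features:
            if f.canonical_name == canonical_name:
                return f
        return None

    def features_of_kind(self, kind: str) -> list[Feature]:
        return [f for f in self.features if f.kind == kind]


# ---------------------------------------------------------------------------
# Gene-name canonicalization


class GeneNameMap:
    """Map raw annotation labels to the controlled vocabulary.

    Mapping is total over the 37 standard genes + CR; unrecognized labels
    map to ``other`` with a warning.  Leucine/serine tRNAs are disambiguated
    by anticodon when available, else by genomic context (handled by
    :func:`read_genbank`).
    """

    _PCG_ALIASES = {
        "ND1": "nad1", "ND2": "nad2", "ND3": "nad3", "ND4": "nad4",
        "ND4L": "nad4l", "ND5": "nad5", "ND6": "nad6",
        "NAD1": "nad1", "NAD2": "nad2", "NAD3": "nad3", "NAD4": "nad4",
        "NAD4L": "nad4l", "NAD5": "nad5", "NAD6": "nad6",
        "NADH1": "nad1", "NADH2": "nad2", "NADH3": "nad3", "NADH4": "nad4",
        "NADH4L": "nad4l", "NADH5": "nad5", "NADH6": "nad6",
        "COX1": "cox1", "COX2": "cox2", "COX3": "cox3",
        "COI": "cox1", "COII": "cox2", "COIII": "cox3",
        "CO1": "cox1", "CO2": "cox2", "CO3": "cox3",
        "COXI": "cox1", "COXII": "cox2", "COXIII": "cox3",
        "ATP6": "atp6", "ATP8": "atp8", "ATPASE6": "atp6", "ATPASE8": "atp8",
        "CYTB": "cob", "CYB": "cob", "COB": "cob",
    }

    def canonical(self, label: str, anticodon: str | None = None) -> str:
        """Return the canonical token for a raw label, or ``other``."""
        raw = label.strip()
        up = re.sub(r"[\s_-]+", "", raw.upper())
        if up in self._PCG_ALIASES:
            return self._PCG_ALIASES[up]
        low = raw.lower()
        if "control" in low or "d-loop" in low or up in ("CR", "DLOOP"):
            return "CR"
        if re.search(r"12S|RRNS|SMALL\s*SUBUNIT|S-?RRNA", raw.upper()):
            return "rrnS"
        if re.search(r"16S|RRNL|LARGE\s*SUBUNIT|L-?RRNA", raw.upper()):
            return "rrnL"
        trna = self._trna(raw, anticodon)
        if trna is not None:
            return trna
        warnings.warn(f"unrecognized gene label {label!r} mapped to 'other'")
        return "other"

    def _trna(self, raw: str, anticodon: str | None) -> str | None:
        m = re.match(r"(?:TRN|TRNA[\s_-]*)([A-Z])\b", raw.upper())
        aa3 = None
        m3 = re.search(r"TRNA[\s_-]*([A-Z]{3})", raw.upper())
        if m3:
            aa3 = m3.group(1)
        if anticodon:
            ac = anticodon.upper().replace("U", "T")
            if ac in _ANTICODON_TO_TRNA:
                return _ANTICODON_TO_TRNA[ac]
        if aa3 in _AA3_TO_TRNA:
            return _AA3_TO_TRNA[aa3]
        if aa3 == "LEU":
            return self._paren_variant(raw, "trnL")
        if aa3 == "SER":
            return self._paren_variant(raw, "trnS")
        if m and aa3 is None:
            letter = m.group(1)
            for name in TRNA_NAMES:
                if name == f"trn{letter}":
                    return name
            if letter == "L":
                return self._paren_variant(raw, "trnL")
            if letter == "S":
                return self._paren_variant(raw, "trnS")
        return None

    @staticmethod
    def _paren_variant(raw: str, base: str) -> str | None:
        up = raw.upper()
        for tag in ("UUR", "TTR"):
            if tag in up:
                return "trnL(uur)"
        if "CUN" in up or "CTN" in up:
            return "trnL(cun)"
        if "UCN" in up or "TCN" in up:
            return "trnS(ucn)"
        if "AGY" in up or "AGC" in up:
            return "trnS(agy)"
        # undisambiguated Leu/Ser: resolved later by context
        return base + "(?)"


DEFAULT_NAME_MAP = GeneNameMap()


# ---------------------------------------------------------------------------
# GenBank I/O


def _label_of(bio_feature: SeqFeature) -> str:
    q = bio_feature.qualifiers
    for key in ("gene", "product", "note", "standard_name"):
        if key in q and q[key]:
            return str(q[key][0])
    return bio_feature.type


def _anticodon_of(bio_feature: SeqFeature) -> str | None:
    q = bio_feature.qualifiers
    if "anticodon" in q and q["anticodon"]:
        m = re.search(r"seq:\s*([acgtu]{3})", q["anticodon"][0], re.I)
        if m:
            return m.group(1).upper().replace("U", "T")
        m = re.fullmatch(r"[ACGTUacgtu]{3}", q["anticodon"][0].strip())
        if m:
            return m.group(0).upper().replace("U", "T")
    for key in ("note", "product"):
        if key in q and q[key]:
            m = re.search(r"anticodon[:\s]*([ACGTUacgtu]{3})", q[key][0], re.I)
            if m:
                return m.group(1).upper().replace("U", "T")
    return None


_KIND_BY_TYPE = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA"}


def _resolve_leu_ser_by_context(features: list[Feature]) -> None:
    """Assign trnL/trnS variants left ambiguous by label and anticodon.

    In the standard vertebrate order trnL(uur) follows rrnL, trnS(ucn)
    follows cox1, and trnS(agy)/trnL(cun) sit in the H-S-L cluster after
    trnH.  Falls back to order of occurrence (uur/ucn first).
    """
    order = [f.canonical_name for f in features]

    def neighbor(idx: int, offset: int) -> str | None:
        j = idx + offset
        return order[j] if 0 <= j < len(order) else None

    for base, first, second in (("trnL", "trnL(uur)", "trnL(cun)"),
                                ("trnS", "trnS(ucn)", "trnS(agy)")):
        pending = [i for i, n in enumerate(order) if n == base + "(?)"]
        for i in pending:
            prev, nxt = neighbor(i, -1), neighbor(i, 1)
            if base == "trnL":
                name = "trnL(uur)" if prev == "rrnL" or nxt == "nad1" else (
                    "trnL(cun)" if prev == "trnS(agy)" or nxt == "nad5" else None)
            else:
                name = "trnS(ucn)" if prev == "cox1" or nxt == "trnD" else (
                    "trnS(agy)" if prev == "trnH" or nxt == "trnL(cun)" else None)
            if name is None:
                taken = {order[j] for j in range(len(order)) if j != i}
                name = first if first not in taken else second
            features[i].canonical_name = name
            order[i] = name


def _convert_location(loc) -> tuple[list[tuple[int, int]], str]:
    """Biopython location -> (intervals in gene 5'->3' order, strand)."""
    strand = "N" if loc.strand == -1 else "J"
    if isinstance(loc, CompoundLocation):
        parts = [(int(p.start), int(p.end)) for p in loc.parts]
    else:
        parts = [(int(loc.start), int(loc.end))]
    return parts, strand


def read_genbank(path, name_map: GeneNameMap = DEFAULT_NAME_MAP) -> list[GenomeRecord]:
    """Parse a GenBank flat file into :class:`GenomeRecord` objects.

    Coordinates arrive 1-based inclusive in the file and are exposed 0-based
    half-open; ``complement`` strands map to ``N``; ``join()`` locations
    become multi-interval features; gene names are canonicalized.
    """
    records: list[GenomeRecord] = []
    for rec in SeqIO.parse(str(path), "genbank"):
        feats: list[Feature] = []
        for bf in rec.features:
            if bf.type in ("source", "gene", "misc_feature", "D-loop"):
                if bf.type == "gene":
                    continue
                label = _label_of(bf)
                if bf.type == "D-loop" or "control" in label.lower() \
                        or "d-loop" in label.lower():
                    intervals, strand = _convert_location(bf.location)
                    feats.append(Feature("CR", "CR", strand, intervals,
                                         raw_label=label))
                continue
            if bf.type not in _KIND_BY_TYPE:
                continue
            label = _label_of(bf)
            anticodon = _anticodon_of(bf) if bf.type == "tRNA" else None
            name = name_map.canonical(label, anticodon)
            kind = _KIND_BY_TYPE[bf.type]
            if name == "other":
                kind = "other"
            intervals, strand = _convert_location(bf.location)
            offset = None
            if bf.type == "CDS":
                cs = bf.qualifiers.get("codon_start", ["1"])
                offset = int(cs[0]) - 1
            feats.append(Feature(name, kind, strand, intervals,
                                 reading_offset=offset, anticodon=anticodon,
                                 raw_label=label))
        _resolve_leu_ser_by_context(feats)
        circular = rec.annotations.get("topology", "circular") == "circular"
        if not feats:
            warnings.warn(f"record {rec.id}: no features found")
        records.append(GenomeRecord(rec.id, str(rec.seq), circular, feats))
    return records


def write_genbank(records: Iterable[GenomeRecord], path) -> None:
    """Write records as GenBank flat files (used by the simulator)."""
    out = []
    for rec in records:
        sr = SeqRecord(Seq(rec.sequence), id=rec.identifier,
                       name=rec.identifier[:16], description="")
        sr.annotations["molecule_type"] = "DNA"
        sr.annotations["topology"] = "circular" if rec.circular else "linear"
        for f in rec.features:
            strand = -1 if f.strand == "N" else 1
            locs = [SimpleLocation(s, e, strand) for s, e in f.intervals]
            loc = locs[0] if len(locs) == 1 else CompoundLocation(locs)
            ftype = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA",
                     "CR": "D-loop"}.get(f.kind, "misc_feature")
            quals = {"gene": [f.canonical_name]}
            if f.kind == "PCG":
                quals["codon_start"] = [str((f.reading_offset or 0) + 1)]
            if f.anticodon:
                quals["note"] = [f"anticodon:{f.anticodon}"]
            sr.features.append(SeqFeature(loc, type=ftype, qualifiers=quals))
        out.append(sr)
    SeqIO.write(out, str(path), "genbank")


def extract_feature_sequence(rec: GenomeRecord, f: Feature) -> str:
    """Feature sequence in gene orientation (N-strand reverse-complemented).

    Intervals are concatenated in order; wrapping across the origin of a
    circular record is expressed by the feature's own two intervals.
    """
    parts = []
    for s, e in f.intervals:
        if not (0 <= s < e <= rec.length):
            raise ValueError(f"interval ({s},{e}) out of bounds for "
                             f"{rec.identifier} (length {rec.length})")
        parts.append(rec.sequence[s:e])
    seq = "".join(parts)
    return reverse_complement(seq) if f.strand == "N" else seq


# ---------------------------------------------------------------------------
# FASTA I/O (gapped sequences allowed)


def write_fasta(seqs: dict[str, str] | Sequence[tuple[str, str]], path,
                width: int = 60) -> None:
    items = list(seqs.items()) if isinstance(seqs, dict) else list(seqs)
    names = [n for n, _ in items]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate sequence names: {dupes}")
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                name = line[1:].split()[0] if line[1:].split() else line[1:]
                if name in seqs:
                    raise ValueError(f"duplicate sequence name {name!r}")
                seqs[name] = ""
            elif name is not None:
                seqs[name] += line.strip()
    return seqs


def feature_table(rec: GenomeRecord):
    """Per-record feature dump: name, kind, strand, start, end, length."""
    import pandas as pd

    rows = [
        {"name": f.canonical_name, "kind": f.kind, "strand": f.strand,
         "start": f.start, "end": f.end, "length": f.length}
        for f in rec.features
    ]
    return pd.DataFrame(rows, columns=["name", "kind", "strand", "start",
                                       "end", "length"])
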