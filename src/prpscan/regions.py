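"""Bait-region partition and per-region pairwise sequence identity.

A2M-family protease inhibitors carry a short internal "bait" segment
(roughly 3-4% of the chain) whose cleavage by a protease springs the trap
conformation.  This module splits a sequence (or an alignment frame) into
region I (upstream of the bait), region II (the bait itself) and region III
(downstream), aligns homolog pairs globally, and counts identical columns
per region, the layout of the published nucleotide/protein homology table.

Coordinates are 1-based and inclusive throughout, the numbering style of
the domain-scheme figure; converters to 0-based half-open slices live at
the I/O boundary only (`RegionPartition.slice_`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "AlphabetError",
    "RegionPartition",
    "PairwiseAlignment",
    "RegionIdentity",
    "partition_sequence",
    "global_align",
    "region_identity",
    "progressive_align",
]

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYXBZUJO*")
NUCLEOTIDE_ALPHABET = set("ACGTUNRYSWKMBDHV")
REGIONS = ("I", "II", "III")


class AlphabetError(ValueError):
    """Sequence contains characters outside the declared alphabet."""


@dataclass(frozen=True)
class RegionPartition:
    """I / II(bait) / III split of one sequence of length ``length``.

    Regions are contiguous, disjoint and covering: I = [1, bait_start-1],
    II = [bait_start, bait_end], III = [bait_end+1, length].  I and/or III
    may be empty.
    """

    seq_id: str
    length: int
    bait_start: int
    bait_end: int

    def __post_init__(self) -> None:
        if not (1 <= self.bait_start <= self.bait_end <= self.length):
            raise ValueError(
                f"{self.seq_id}: bait [{self.bait_start}, {self.bait_end}] outside "
                f"sequence of length {self.length}"
            )

    def bounds(self, region: str) -> tuple[int, int]:
        """1-based inclusive (start, end); end < start marks an empty region."""
        return {
            "I": (1, self.bait_start - 1),
            "II": (self.bait_start, self.bait_end),
            "III": (self.bait_end + 1, self.length),
        }[region]

    def slice_(self, region: str) -> slice:
        """0-based half-open slice for the region."""
        start, end = self.bounds(region)
        return slice(start - 1, end)

    def region_length(self, region: str) -> int:
        start, end = self.bounds(region)
        return max(0, end - start + 1)

    def region_of(self, position: int) -> str:
        """Region containing a 1-based position."""
        if not 1 <= position <= self.length:
            raise ValueError(f"position {position} outside [1, {self.length}]")
        if position < self.bait_start:
            return "I"
        if position <= self.bait_end:
            return "II"
        return "III"

    def fraction_pct(self, region: str, ndigits: int = 1) -> float:
        """Region length as % of total, to ``ndigits`` decimals."""
        return round(100.0 * self.region_length(region) / self.length, ndigits)


def partition_sequence(
    length: int, bait_start: int, bait_end: int, seq_id: str = "seq"
) -> RegionPartition:
    """Build the three-region partition for a sequence of ``length``."""
    return RegionPartition(seq_id=seq_id, length=int(length), bait_start=int(bait_start), bait_end=int(bait_end))


# --- pairwise global alignment -------------------------------------------

#: BLOSUM62 with affine gaps (BLASTp-style costs) for proteins; a simple
#: match/mismatch scheme with affine gaps for nucleotides.  IUPAC ambiguity
#: codes are accepted on input and can only score as mismatches.
DEFAULT_PARAMS = {
    "protein": {"matrix": "BLOSUM62", "open": -11.0, "extend": -1.0},
    "nucleotide": {"match": 2.0, "mismatch": -3.0, "open": -5.0, "extend": -2.0},
}


@dataclass
class PairwiseAlignment:
    """A global alignment as two equal-length gapped strings."""

    a: str
    b: str
    score: float
    level: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.a) != len(self.b):
            raise ValueError("gapped sequences must have equal length")

    def __len__(self) -> int:
        return len(self.a)

    def ungapped(self) -> tuple[str, str]:
        return self.a.replace("-", ""), self.b.replace("-", "")

    def column_classes(self) -> list[str]:
        """Per column: 'match', 'mismatch' or 'gap'."""
        out = []
        for x, y in zip(self.a, self.b):
            if x == "-" or y == "-":
                out.append("gap")
            elif x.upper() == y.upper():
                out.append("match")
            else:
                out.append("mismatch")
        return out

    def ref_coordinates(self) -> list[int | None]:
        """1-based coordinate in the first (reference) sequence per column."""
        out: list[int | None] = []
        i = 0
        for x in self.a:
            if x == "-":
                out.append(None)
            else:
                i += 1
                out.append(i)
        return out


def _check_alphabet(seq: str, level: str) -> None:
    alphabet = PROTEIN_ALPHABET if level == "protein" else NUCLEOTIDE_ALPHABET
    bad = set(seq.upper()) - alphabet
    if bad:
        raise AlphabetError(f"illegal {level} characters: {sorted(bad)}")


def make_aligner(level: str = "protein", params: dict | None = None) -> Align.PairwiseAligner:
    if level not in DEFAULT_PARAMS:
        raise ValueError(f"level must be 'protein' or 'nucleotide', got {level!r}")
    p = dict(DEFAULT_PARAMS[level], **(params or {}))
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if level == "protein":
        matrix = substitution_matrices.load(p["matrix"])
        # extend to the full observed alphabet so X/B/Z/U/J/O do not crash
        aligner.substitution_matrix = matrix
        aligner.wildcard = "X"
    else:
        aligner.match_score = p["match"]
        aligner.mismatch_score = p["mismatch"]
        aligner.wildcard = "N"
    aligner.open_gap_score = p["open"]
    aligner.extend_gap_score = p["extend"]
    return aligner


def global_align(
    a: str, b: str, level: str = "protein", params: dict | None = None
) -> PairwiseAlignment:
    """Optimal global alignment of two sequences.

    Deterministic: of the co-optimal alignments Biopython enumerates in a
    fixed order, the first is returned.  An empty partner yields the
    all-gap alignment.
    """
    a, b = str(a).upper(), str(b).upper()
    _check_alphabet(a, level)
    _check_alphabet(b, level)
    if not a or not b:
        return PairwiseAlignment(
            a=a or "-" * len(b), b=b or "-" * len(a), score=0.0, level=level,
            params=dict(DEFAULT_PARAMS[level], **(params or {})),
        )
    if level == "protein":
        # residues missing from BLOSUM62 (U, O, J) are aligned as X
        trans = str.maketrans({"U": "X", "O": "X", "J": "X"})
        a_s, b_s = a.translate(trans), b.translate(trans)
    else:
        ambiguous = NUCLEOTIDE_ALPHABET - set("ACGT")
        trans = str.maketrans({c: "N" for c in ambiguous})
        a_s, b_s = a.translate(trans), b.translate(trans)
    aligner = make_aligner(level, params)
    aln = aligner.align(a_s, b_s)[0]
    ga, gb = str(aln[0]), str(aln[1])
    # restore the original (possibly ambiguous) letters
    ga = _regap(a, ga)
    gb = _regap(b, gb)
    return PairwiseAlignment(
        a=ga, b=gb, score=float(aln.score), level=level,
        params=dict(DEFAULT_PARAMS[level], **(params or {})),
    )


def _regap(original: str, gapped: str) -> str:
    it = iter(original)
    return "".join("-" if c == "-" else next(it) for c in gapped)


@dataclass(frozen=True)
class RegionIdentity:
    """Identical-column count over a region, with an explicit denominator."""

    region: str
    matches: int
    denominator: int
    level: str
    denominator_mode: str

    @property
    def identity_pct(self) -> float:
        return 100.0 * self.matches / self.denominator if self.denominator else float("nan")


def region_identity(
    aln: PairwiseAlignment,
    part: RegionPartition,
    denominator_mode: str = "region-length",
) -> dict[str, RegionIdentity]:
    """Identity per region (and 'total'), regions taken on the reference.

    The partition refers to the first sequence of the alignment; each
    column is assigned to the region containing its reference coordinate
    (columns where the reference is gapped are attributed to the region of
    the next reference residue, i.e. insertions sit with the region they
    precede; trailing insertions go to region III).  ``denominator_mode``:

    * ``region-length`` (default, the published table's convention):
      denominator is the region's length in reference residues;
    * ``aligned-columns``: denominator is the number of gap-free columns of
      the region, which makes identity symmetric in the two sequences.

    Empty regions are reported as absent (missing from the result).
    """
    if denominator_mode not in ("region-length", "aligned-columns"):
        raise ValueError(f"unknown denominator_mode {denominator_mode!r}")
    if part.length != len(aln.ungapped()[0]):
        raise ValueError(
            f"partition length {part.length} != reference length {len(aln.ungapped()[0])}"
        )
    matches = {r: 0 for r in REGIONS}
    aligned_cols = {r: 0 for r in REGIONS}
    classes = aln.column_classes()
    coords = aln.ref_coordinates()
    # forward-fill insertion columns onto the next reference coordinate
    next_coord: list[int] = [part.length + 1] * len(coords)
    upcoming = part.length + 1
    for i in range(len(coords) - 1, -1, -1):
        if coords[i] is not None:
            upcoming = coords[i]
        next_coord[i] = upcoming
    for cls, pos in zip(classes, next_coord):
        region = part.region_of(min(pos, part.length))
        if cls != "gap":
            aligned_cols[region] += 1
        if cls == "match":
            matches[region] += 1
    out: dict[str, RegionIdentity] = {}
    for r in REGIONS:
        denom = part.region_length(r) if denominator_mode == "region-length" else aligned_cols[r]
        if part.region_length(r) == 0:
            continue
        out[r] = RegionIdentity(r, matches[r], denom, aln.level, denominator_mode)
    total_denom = (
        part.length if denominator_mode == "region-length" else sum(aligned_cols.values())
    )
    out["total"] = RegionIdentity(
        "total", sum(matches.values()), total_denom, aln.level, denominator_mode
    )
    return out


# --- progressive multi-sequence alignment --------------------------------

def progressive_align(
    seqs: list[str], level: str = "protein", params: dict | None = None
) -> list[str]:
    """Simple progressive global alignment, guide order = input order.

    Each sequence is aligned pairwise against the running profile's
    consensus (majority letter per column, ignoring gaps) and the resulting
    gaps are propagated into all profile members.  This is a deliberately
    lightweight stand-in for a full MSA program and is adequate for the
    closely related sequence sets this package analyses; it is documented
    as approximate.
    """
    if not seqs:
        return []
    profile = [str(seqs[0]).upper()]
    for seq in seqs[1:]:
        consensus = _consensus(profile)
        aln = global_align(consensus, str(seq).upper(), level=level, params=params)
        new_profile = []
        for member in profile:
            it = iter(member)
            new_profile.append("".join("-" if c == "-" else next(it) for c in aln.a))
        new_profile.append(aln.b)
        profile = new_profile
    return profile


def _consensus(profile: list[str]) -> str:
    out = []
    for col in zip(*profile):
        letters = [c for c in col if c != "-"]
        if not letters:
            continue
        counts: dict[str, int] = {}
        for c in letters:
            counts[c] = counts.get(c, 0) + 1
        out.append(max(sorted(counts), key=counts.get))
    return "".join(out)
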