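"""Deterministic protease cleavage-site rule engine.

Each protease is a pure predicate over the six-residue substrate window
P4-P3-P2-P1 | P1'-P2' (cleavage between P1 and P1').  The rules are data,
shipped as a packaged YAML table encoding the publicly documented
specificities of the in-silico digestion tool the bait-region accessibility
analysis relies on; editing the YAML changes the engine's behaviour without
touching code.

Positions index the P1 residue (the residue after which the bond is cut),
1-based.  A predicate can never fire across a terminus: both P1 and P1'
must exist, so positions lie in [1, L-1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd
import yaml

from .regions import RegionPartition

__all__ = [
    "CleavageRule",
    "CleavageSiteSet",
    "builtin_rules",
    "load_rules",
    "find_sites",
    "digest",
    "accessibility",
]

AA20 = set("ACDEFGHIKLMNPQRSTVWY")
#: residues that never satisfy a required set and never trigger an exception
AMBIGUOUS = set("XBZUJO")

#: slot name -> offset from the P1 residue (0-based within the sequence)
SLOT_OFFSETS = {"P4": -3, "P3": -2, "P2": -1, "P1": 0, "P1prime": 1, "P2prime": 2}


class AlphabetError(ValueError):
    """Residue codes outside the amino-acid alphabet (plus ambiguity codes)."""


@dataclass(frozen=True)
class CleavageRule:
    """One enzyme's cleavage predicate.

    ``clauses`` are cleavage candidates (any may match), ``exceptions``
    block a candidate match, ``overrides`` fire regardless of clauses and
    exceptions.  Every slot constraint is either ``{"in": residues}``
    (residue must exist and be in the set) or ``{"not_in": residues}``
    (residue, if it exists, must not be in the set).
    """

    name: str
    clauses: tuple[dict, ...]
    exceptions: tuple[dict, ...] = ()
    overrides: tuple[dict, ...] = ()
    provenance: str = ""
    default: bool = True

    def matches(self, seq: str, position: int) -> bool:
        """Does this enzyme cut after the 1-based ``position``?"""
        if not 1 <= position <= len(seq) - 1:
            return False
        if any(_clause_matches(c, seq, position, required_ctx=True) for c in self.overrides):
            return True
        if not any(_clause_matches(c, seq, position, required_ctx=True) for c in self.clauses):
            return False
        return not any(
            _clause_matches(c, seq, position, required_ctx=False) for c in self.exceptions
        )


def _clause_matches(clause: dict, seq: str, position: int, required_ctx: bool) -> bool:
    """Evaluate one slot-set clause at a 1-based P1 ``position``.

    ``required_ctx`` distinguishes positive clauses (an ``in`` slot whose
    residue falls outside the sequence fails the clause) from exception
    clauses, where the same situation simply cannot trigger the exception
    (identical outcome; the flag is kept for clarity of intent).
    """
    for slot, constraint in clause.items():
        offset = SLOT_OFFSETS[slot]
        idx = position - 1 + offset
        residue = seq[idx] if 0 <= idx < len(seq) else None
        if "in" in constraint:
            if residue is None or residue in AMBIGUOUS or residue not in set(constraint["in"]):
                return False
        if "not_in" in constraint:
            if residue is not None and residue not in AMBIGUOUS and residue in set(constraint["not_in"]):
                return False
    return True


def _parse_rule(entry: dict) -> CleavageRule:
    def norm(clauses):
        out = []
        for c in clauses or []:
            bad = set(c) - set(SLOT_OFFSETS)
            if bad:
                raise ValueError(f"unknown slots {sorted(bad)} in rule {entry.get('name')!r}")
            out.append({k: dict(v) for k, v in c.items()})
        return tuple(out)

    return CleavageRule(
        name=entry["name"],
        clauses=norm(entry.get("clauses")),
        exceptions=norm(entry.get("exceptions")),
        overrides=norm(entry.get("overrides")),
        provenance=entry.get("provenance", "").strip(),
        default=bool(entry.get("default", True)),
    )


def load_rules(path=None, include_non_default: bool = False) -> list[CleavageRule]:
    """Load cleavage rules from YAML (the packaged table by default)."""
    if path is None:
        text = resources.files("prpscan.data").joinpath("cleavage_rules.yml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    entries = yaml.safe_load(text)["rules"]
    rules = [_parse_rule(e) for e in entries]
    if not include_non_default:
        rules = [r for r in rules if r.default]
    return rules


def builtin_rules() -> list[CleavageRule]:
    """The default 13-enzyme panel of the accessibility table."""
    return load_rules()


@dataclass(frozen=True)
class CleavageSiteSet:
    """Sorted 1-based P1 positions at which one enzyme cuts one sequence."""

    seq_id: str
    enzyme: str
    positions: tuple[int, ...]

    def __post_init__(self) -> None:
        if list(self.positions) != sorted(set(self.positions)):
            raise ValueError("positions must be strictly increasing")

    def fragments(self, seq: str) -> list[str]:
        """Peptide fragments produced by cutting after every position."""
        cuts = [0, *self.positions, len(seq)]
        return [seq[a:b] for a, b in zip(cuts, cuts[1:]) if b > a]


def _check_protein(seq: str) -> str:
    seq = str(seq).upper()
    bad = set(seq) - AA20 - AMBIGUOUS
    if bad:
        raise AlphabetError(f"illegal residue codes: {sorted(bad)}")
    return seq


def find_sites(seq: str, rule: CleavageRule) -> CleavageSiteSet:
    """All P1 positions where ``rule`` predicts cleavage, deterministically."""
    s = _check_protein(seq)
    positions = tuple(i for i in range(1, len(s)) if rule.matches(s, i))
    return CleavageSiteSet(seq_id="", enzyme=rule.name, positions=positions)


def digest(seq: str, rule: CleavageRule) -> list[str]:
    """Peptide fragments of ``seq`` under ``rule``."""
    return find_sites(seq, rule).fragments(_check_protein(seq))


def accessibility(
    sequences: dict[str, str],
    partitions: dict[str, RegionPartition],
    rules: list[CleavageRule] | None = None,
    column_order: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bait-region accessibility matrix: enzymes x proteins.

    A cell is ``+`` iff at least one predicted site has its P1 residue
    inside region II (the bait) of that protein; prediction runs on the
    full-length sequence and is then intersected with the bait window, so
    the bait's edge residues see their true flanking context.  Returns the
    ``+``/``-`` matrix and the parallel matrix of within-bait site counts.
    """
    rules = builtin_rules() if rules is None else rules
    cols = column_order or list(sequences)
    missing = [c for c in cols if c not in partitions]
    if missing:
        raise KeyError(f"no bait-region partition for: {missing}")
    marks = pd.DataFrame(index=[r.name for r in rules], columns=cols, dtype=object)
    counts = pd.DataFrame(0, index=[r.name for r in rules], columns=cols, dtype=int)
    for col in cols:
        seq = _check_protein(sequences[col])
        part = partitions[col]
        if part.length != len(seq):
            raise ValueError(f"{col}: partition length {part.length} != sequence length {len(seq)}")
        lo, hi = part.bounds("II")
        for rule in rules:
            sites = find_sites(seq, rule)
            inside = [p for p in sites.positions if lo <= p <= hi]
            counts.loc[rule.name, col] = len(inside)
            marks.loc[rule.name, col] = "+" if inside else "-"
    return marks, counts
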