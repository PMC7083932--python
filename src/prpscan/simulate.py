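"""Seeded synthetic-data generators for every pipeline stage.

The generators reproduce the statistical structure the analysis stages
assume, so the whole pipeline can be exercised end-to-end without any
sequence or proteomics download:

* :func:`gen_abundance` -- spectral-count tables with an invariant albumin
  channel, planted trimester trajectories per category (second-trimester
  surges, undetectable baselines, declines) and multiplicative lognormal
  noise, the standard noise model for spectral counts; hard zeros arise
  from a detection limit.
* :func:`gen_homolog_pair` -- an ancestor/descendant coding-sequence pair
  with an elevated per-residue substitution rate inside a designated bait
  window; the emitted protein is always the translation of the emitted CDS
  and the true per-region mismatch counts are returned.
* :func:`gen_snps` -- variant tables with a region-dependent density
  (bait enrichment) and a configurable missense fraction.

Every generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from .quant import SpectralCountTable
from .regions import RegionPartition

__all__ = [
    "AbundanceSimConfig",
    "HomologPairConfig",
    "gen_abundance",
    "gen_homolog_pair",
    "gen_snps",
]

#: trimester fold-change profiles that plant each trajectory category; the
#: increase profiles exceed the 2x rule and the decrease profiles fall
#: below the 0.5x rule with margin comparable to the published table
CATEGORY_PROFILES: dict[str, tuple[float, float, float]] = {
    "1a": (1.0, 5.0, 2.5),
    "1b": (1.0, 2.0, 5.0),
    "2a": (1.0, 0.25, 0.5),
    "2b": (1.0, 0.5, 0.25),
    "unchanged": (1.0, 1.0, 1.0),
}


@dataclass
class AbundanceSimConfig:
    """Configuration of the spectral-count simulator.

    ``n_per_category`` plants that many proteins per trajectory category;
    ``undetectable_fraction`` of category-1 proteins start below the
    detection limit (the "undetectable baseline, second-trimester surge"
    pattern).  ``sigma`` is the lognormal noise on each count;
    ``detection_limit`` is in relative-amount units (albumin = ``scale``).
    """

    n_per_category: dict[str, int] = field(
        default_factory=lambda: {c: 10 for c in CATEGORY_PROFILES}
    )
    subjects: int = 3
    base_level: float = 5.0  # relative-amount units of a detectable baseline
    undetectable_base: float = 0.2  # baseline of surge-from-zero proteins
    undetectable_fraction: float = 0.3
    sigma: float = 0.3
    detection_limit: float = 0.5
    reference_count: int = 480
    scale: float = 100.0
    reference_id: str = "ALBU"
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.n_per_category) - set(CATEGORY_PROFILES)
        if unknown:
            raise ValueError(f"unknown categories: {sorted(unknown)}")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


def gen_abundance(cfg: AbundanceSimConfig) -> tuple[SpectralCountTable, pd.Series]:
    """Simulate a spectral-count table plus the true category labels.

    count = round(reference_count * relative_amount / scale) with
    relative_amount = base * trimester_fold * lognormal(sigma), zeroed
    below the detection limit.  Sample columns are named S<subject>T<tri>.
    """
    rng = np.random.default_rng(cfg.seed)
    samples = [
        (f"S{s + 1}T{t}", s + 1, t)
        for s in range(cfg.subjects)
        for t in (1, 2, 3)
    ]
    design = pd.DataFrame(
        {
            "subject": [s for _, s, _ in samples],
            "trimester": [t for _, _, t in samples],
            "species": "synthetic",
            "pregnant": True,
        },
        index=[name for name, _, _ in samples],
    )
    rows: dict[str, list[float]] = {}
    truth: dict[str, str] = {}
    rows[cfg.reference_id] = [float(cfg.reference_count)] * len(samples)
    for category in CATEGORY_PROFILES:
        n = cfg.n_per_category.get(category, 0)
        folds = CATEGORY_PROFILES[category]
        n_undetectable = (
            round(cfg.undetectable_fraction * n) if category in ("1a", "1b") else 0
        )
        for k in range(n):
            pid = f"{category.upper()}_{k + 1:03d}"
            surge_from_zero = k < n_undetectable
            base = cfg.undetectable_base if surge_from_zero else cfg.base_level
            boost = 25.0 if surge_from_zero else 1.0  # keeps the surge >= 1
            counts = []
            for _, _, t in samples:
                rel = base * folds[t - 1] * (boost if t > 1 else 1.0)
                rel *= float(np.exp(rng.normal(0.0, cfg.sigma)))
                if rel < cfg.detection_limit:
                    rel = 0.0
                counts.append(float(round(cfg.reference_count * rel / cfg.scale)))
            rows[pid] = counts
            truth[pid] = category
    counts_df = pd.DataFrame.from_dict(
        rows, orient="index", columns=[name for name, _, _ in samples]
    )
    table = SpectralCountTable(counts=counts_df, design=design)
    return table, pd.Series(truth, name="category")


# --- homologous sequence pairs -------------------------------------------

_AA_TO_CODONS: dict[str, list[str]] = {}
for _codon, _aa in sorted(standard_dna_table.forward_table.items()):
    _AA_TO_CODONS.setdefault(_aa, []).append(_codon)
_AMINO_ACIDS = sorted(_AA_TO_CODONS)


@dataclass
class HomologPairConfig:
    """Ancestor/descendant pair with planted per-region divergence.

    ``r_out`` / ``r_bait`` are per-residue amino-acid substitution
    probabilities outside/inside the bait window (protein coordinates,
    1-based inclusive).  ``indel_rate`` is the per-residue probability of
    deleting a codon in the descendant (0 by default: the identity
    bookkeeping is then exact per site).
    """

    length: int = 1491  # residues
    bait_start: int = 683
    bait_end: int = 738
    r_out: float = 0.05
    r_bait: float = 0.4
    indel_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.bait_start <= self.bait_end <= self.length:
            raise ValueError("bait window outside sequence")
        for r in (self.r_out, self.r_bait, self.indel_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.r_bait < self.r_out:
            raise ValueError("r_bait must be >= r_out")

    def partition(self, seq_id: str = "descendant") -> RegionPartition:
        return RegionPartition(seq_id, self.length, self.bait_start, self.bait_end)


def gen_homolog_pair(cfg: HomologPairConfig) -> dict:
    """Simulate the pair; returns sequences plus true per-region counts.

    The descendant is mutated codon-wise: with the region's substitution
    probability the amino acid is replaced by a different residue and the
    codon re-encoded (first/second codon positions change, which keeps the
    substitution nonsynonymous while CDS and protein stay consistent).
    Returns a dict with ancestor/descendant CDS and protein strings, the
    bait partition, and true mismatch counts per region.
    """
    rng = np.random.default_rng(cfg.seed)
    aa_anc = rng.choice(_AMINO_ACIDS, size=cfg.length)
    codons_anc = [
        codons[rng.integers(len(codons))]
        for codons in (_AA_TO_CODONS[a] for a in aa_anc)
    ]
    part = cfg.partition()
    aa_desc: list[str] = []
    codons_desc: list[str] = []
    mismatches = {"I": 0, "II": 0, "III": 0}
    for pos0, aa in enumerate(aa_anc):
        region = part.region_of(pos0 + 1)
        rate = cfg.r_bait if region == "II" else cfg.r_out
        if rng.random() < rate:
            new_aa = aa
            while new_aa == aa:
                new_aa = _AMINO_ACIDS[rng.integers(len(_AMINO_ACIDS))]
            mismatches[region] += 1
            codons = _AA_TO_CODONS[new_aa]
            aa_desc.append(new_aa)
            codons_desc.append(codons[rng.integers(len(codons))])
        else:
            aa_desc.append(aa)
            codons_desc.append(codons_anc[pos0])
    kept = [
        i for i in range(cfg.length) if cfg.indel_rate == 0 or rng.random() >= cfg.indel_rate
    ]
    cds_desc = "".join(codons_desc[i] for i in kept)
    prot_desc = "".join(aa_desc[i] for i in kept)
    cds_anc = "".join(codons_anc)
    prot_anc = "".join(aa_anc)
    assert str(Seq(cds_desc).translate()) == prot_desc
    assert str(Seq(cds_anc).translate()) == prot_anc
    return {
        "cds_ancestor": cds_anc,
        "cds_descendant": cds_desc,
        "protein_ancestor": prot_anc,
        "protein_descendant": prot_desc,
        "partition": part,
        "true_mismatches": mismatches,
        "n_deleted": cfg.length - len(kept),
    }


def gen_snps(
    length: int,
    bait_start: int,
    bait_end: int,
    base_rate: float = 0.01,
    bait_enrichment: float = 3.0,
    missense_fraction: float = 0.6,
    maf_below_threshold_fraction: float = 0.2,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Simulate a variant table with bait-enriched density.

    Each position carries a variant independently with probability
    ``base_rate`` (flank) or ``base_rate * bait_enrichment`` (bait window,
    1-based inclusive).  Consequences are missense with probability
    ``missense_fraction`` (otherwise synonymous/other); MAFs are drawn
    uniformly on [0.01, 0.5], except a ``maf_below_threshold_fraction`` of
    records drawn on [0.001, 0.01) to exercise the MAF filter.  Returns
    the table plus the planted truth (rates and window).
    """
    part = RegionPartition("synthetic", length, bait_start, bait_end)
    for r in (base_rate, base_rate * bait_enrichment):
        if not 0.0 <= r <= 1.0:
            raise ValueError("rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    records = []
    for pos in range(1, length + 1):
        rate = base_rate * bait_enrichment if part.region_of(pos) == "II" else base_rate
        if rng.random() >= rate:
            continue
        consequence = "missense" if rng.random() < missense_fraction else (
            "synonymous" if rng.random() < 0.8 else "other"
        )
        if rng.random() < maf_below_threshold_fraction:
            maf = float(rng.uniform(0.001, 0.01))
        else:
            maf = float(rng.uniform(0.01, 0.5))
        records.append(
            {"id": f"rs_syn_{pos}", "position": pos, "consequence": consequence,
             "maf": round(maf, 4)}
        )
    df = pd.DataFrame(records, columns=["id", "position", "consequence", "maf"])
    truth = {
        "base_rate": base_rate,
        "bait_enrichment": bait_enrichment,
        "missense_fraction": missense_fraction,
        "partition": part,
    }
    return df, truth
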