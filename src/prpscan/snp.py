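"""Region-wise SNP and missense-substitution density statistics.

Input is a flat table of pre-annotated variants (position, consequence,
minor-allele frequency) in an explicit coordinate space -- protein residues
(``protein-aa``) or mRNA nucleotides (``mRNA-nt``).  Densities are reported
per region of a bait-region partition together with raw counts, region
lengths and the coordinate basis, so any denominator convention can be
audited downstream; the bait-vs-whole and bait-vs-flank enrichment ratios
quantify the concentration of amino-acid-changing variation in the bait.
"""

from __future__ import annotations

import pandas as pd

from .regions import RegionPartition

__all__ = [
    "CONSEQUENCES",
    "read_snp_csv",
    "filter_snps",
    "region_density",
]

CONSEQUENCES = ("missense", "synonymous", "nonsense", "frameshift", "other")
LENGTH_BASES = ("protein-aa", "mRNA-nt")
REQUIRED_COLUMNS = ("position", "consequence", "maf")


def read_snp_csv(path) -> pd.DataFrame:
    """Read a variant table (columns: id, position, consequence, maf)."""
    df = pd.read_csv(path, comment="#")
    return validate_snps(df)


def validate_snps(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"SNP table missing columns: {missing}")
    if ((df["maf"] < 0) | (df["maf"] > 0.5)).any():
        raise ValueError("minor-allele frequencies must lie in [0, 0.5]")
    bad = set(df["consequence"]) - set(CONSEQUENCES)
    if bad:
        raise ValueError(f"unknown consequence labels: {sorted(bad)}")
    return df


def filter_snps(df: pd.DataFrame, maf_min: float = 0.01) -> pd.DataFrame:
    """Keep variants with MAF >= ``maf_min`` (the usual screen is 1%)."""
    if not 0.0 <= maf_min <= 0.5:
        raise ValueError("maf_min must lie in [0, 0.5]")
    validate_snps(df)
    return df[df["maf"] >= maf_min].reset_index(drop=True)


def region_density(
    df: pd.DataFrame,
    partition: RegionPartition,
    length_basis: str,
    consequence_set: tuple[str, ...] = ("missense",),
    dedupe_positions: bool = True,
) -> pd.DataFrame:
    """Per-region SNP counts and consequence densities.

    ``length_basis`` must name the coordinate space the positions live in
    (``protein-aa`` or ``mRNA-nt``) and is stamped into the report; the
    partition must be in the same space (a position outside the partition
    raises, which catches basis mismatches).  ``density_pct`` is
    100 x selected-consequence count / region length.  Duplicate records at
    one position count once by default.

    Returns one row per region (I, II, III) plus ``whole``, ``flank``
    (I+III pooled) and the two enrichment ratios bait/whole and bait/flank.
    """
    if length_basis not in LENGTH_BASES:
        raise ValueError(f"length_basis must be one of {LENGTH_BASES}")
    validate_snps(df)
    unknown = set(consequence_set) - set(CONSEQUENCES)
    if unknown:
        raise ValueError(f"unknown consequences requested: {sorted(unknown)}")
    out_of_range = df[(df["position"] < 1) | (df["position"] > partition.length)]
    if len(out_of_range):
        raise ValueError(
            f"{len(out_of_range)} positions outside [1, {partition.length}]: "
            "coordinate-space mismatch between records and partition?"
        )
    work = df.copy()
    if dedupe_positions:
        work = work.sort_values(["position", "maf"], ascending=[True, False])
        work = work.drop_duplicates(subset="position", keep="first")
    work = work.assign(region=work["position"].map(partition.region_of))
    selected = work[work["consequence"].isin(consequence_set)]

    def row(name: str, snps: pd.DataFrame, hits: pd.DataFrame, length: int) -> dict:
        return {
            "region": name,
            "n_snps": len(snps),
            "n_selected": len(hits),
            "length": length,
            "density_pct": 100.0 * len(hits) / length if length else float("nan"),
            "basis": length_basis,
        }

    rows = [
        row(r, work[work["region"] == r], selected[selected["region"] == r],
            partition.region_length(r))
        for r in ("I", "II", "III")
    ]
    rows.append(row("whole", work, selected, partition.length))
    flank_len = partition.region_length("I") + partition.region_length("III")
    rows.append(
        row("flank", work[work["region"] != "II"], selected[selected["region"] != "II"],
            flank_len)
    )
    rep = pd.DataFrame(rows).set_index("region")
    bait = rep.loc["II", "density_pct"]
    rep["enrichment_bait_vs_whole"] = float("nan")
    rep["enrichment_bait_vs_flank"] = float("nan")
    whole = rep.loc["whole", "density_pct"]
    flank = rep.loc["flank", "density_pct"]
    if whole and whole > 0:
        rep.loc["II", "enrichment_bait_vs_whole"] = bait / whole
    if flank and flank > 0:
        rep.loc["II", "enrichment_bait_vs_flank"] = bait / flank
    return rep
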