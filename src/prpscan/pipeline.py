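"""I/O, configuration and the end-to-end pipeline driver.

Wires the stages together: albumin-referenced quantitation and trajectory
classification, bait-region partition and per-region identity, protease
accessibility of the bait, whole-vs-bait distances/trees, and SNP density.
Every stage is optional -- it runs iff its inputs are configured -- and
every output file embeds the package version and a configuration hash, so
a report bundle is reproducible byte-for-byte from config + seeds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO

from . import __version__
from .cleave import accessibility, builtin_rules, load_rules
from .phylo import bootstrap_support, nj_tree, pairwise_distance, region_vs_whole_report
from .quant import AbundanceTable, SpectralCountTable, normalize_to_reference, pca_projection, trimester_summary
from .regions import RegionPartition, global_align, progressive_align, region_identity
from .snp import filter_snps, read_snp_csv, region_density

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "read_counts_csv",
    "read_design_csv",
    "read_fasta",
    "read_regions_yaml",
    "load_table1_fixture",
    "run_all",
]

logger = logging.getLogger("prpscan")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending record."""


# --- readers --------------------------------------------------------------

def read_counts_csv(path) -> tuple[pd.DataFrame, pd.Series]:
    """Counts CSV: first column accession, second protein name, then samples."""
    df = pd.read_csv(path, comment="#")
    if df.shape[1] < 3:
        raise PipelineError("quant: counts CSV needs accession, name and >=1 sample column")
    df = df.set_index(df.columns[0])
    names = df[df.columns[0]]
    counts = df.drop(columns=df.columns[0]).astype(float)
    return counts, names


def read_design_csv(path) -> pd.DataFrame:
    """Design CSV with columns sample,subject,trimester,species[,pregnant]."""
    df = pd.read_csv(path, comment="#")
    required = {"sample", "subject", "trimester"}
    missing = required - set(df.columns)
    if missing:
        raise PipelineError(f"quant: design CSV missing columns {sorted(missing)}")
    return df.set_index("sample")


def read_fasta(path) -> dict[str, str]:
    """FASTA -> {record id: sequence string}, order-preserving."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_regions_yaml(path=None) -> dict[str, RegionPartition]:
    """Region config (`sequences: [{id, length, bait_start, bait_end}]`)."""
    if path is None:
        text = resources.files("prpscan.data").joinpath("regions.yml").read_text()
    else:
        text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    out = {}
    for entry in cfg["sequences"]:
        out[entry["id"]] = RegionPartition(
            seq_id=entry["id"],
            length=int(entry["length"]),
            bait_start=int(entry["bait_start"]),
            bait_end=int(entry["bait_end"]),
        )
    return out


def load_table1_fixture(species: str = "human") -> tuple[AbundanceTable, pd.DataFrame]:
    """The packaged printed per-sample relative-amount fixture.

    Returns the fixture as an :class:`AbundanceTable` (values are already
    albumin-referenced, so no reference row is present; ``reference_id`` is
    recorded as ``"ALB(printed)"``) together with the printed summary
    columns (category block, means, ratios, p-values) for golden tests.
    """
    if species not in ("human", "marmoset"):
        raise ValueError("species must be 'human' or 'marmoset'")
    path = resources.files("prpscan.data").joinpath(f"table1_{species}.csv")
    with path.open() as fh:
        df = pd.read_csv(fh, comment="#")
    sample_cols = [c for c in df.columns if c.startswith(("t1_", "t2_", "t3_"))]
    values = df.set_index("protein")[sample_cols]
    design = pd.DataFrame(
        {
            "subject": [c.split("_")[1] for c in sample_cols],
            "trimester": [int(c[1]) for c in sample_cols],
            "species": species,
        },
        index=sample_cols,
    )
    printed = df.set_index("protein")[
        [c for c in df.columns if c.startswith("printed_") or c in ("category", "no", "accession")]
    ]
    table = AbundanceTable(
        values=values, design=design, reference_id="ALB(printed)", scale=100.0
    )
    return table, printed


# --- configuration --------------------------------------------------------

_CONFIG_FIELDS: dict[str, object] = {}


@dataclass
class PipelineConfig:
    """Validated configuration of the full pipeline.

    Unknown keys are rejected; the serialised config (and its SHA-256) is
    embedded in every output header for provenance.
    """

    # quant stage
    counts_csv: str | None = None
    design_csv: str | None = None
    reference_id: str = "ALBU"
    scale: float = 100.0
    ttest_variant: str = "welch"
    pca_scaling: str = "unit-variance"
    # regions stage
    fasta: str | None = None
    regions_yml: str | None = None
    level: str = "protein"
    denominator_mode: str = "region-length"
    # cleavage stage
    cleave_fasta: str | None = None
    rules_yml: str | None = None
    # phylogeny stage
    phylo_fasta: str | None = None
    distance_model: str = "poisson"
    bootstrap_reps: int = 0
    bait_columns: tuple[int, int] | None = None
    # SNP stage
    snp_csv: str | None = None
    snp_region_id: str | None = None
    maf_min: float = 0.01
    length_basis: str = "protein-aa"
    # global
    seed: int = 0

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"config: unknown keys {sorted(unknown)}")
        if "bait_columns" in raw and raw["bait_columns"] is not None:
            raw = dict(raw, bait_columns=tuple(raw["bait_columns"]))
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)

    def sha256(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: Path, cfg: PipelineConfig, index: bool = True) -> None:
    header = f"# prpscan {__version__} config_sha256={cfg.sha256()}\n"
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        fh.write(header)
        df.to_csv(fh, index=index)


def _write_text(text: str, path: Path, cfg: PipelineConfig) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# prpscan {__version__} config_sha256={cfg.sha256()}\n")
        fh.write(text if text.endswith("\n") else text + "\n")


# --- driver ---------------------------------------------------------------

def run_all(cfg: PipelineConfig, outdir) -> dict[str, Path]:
    """Run every configured stage; returns {output name: path}.

    Deterministic given config + seeds.  Any stage failure raises
    :class:`PipelineError` naming the stage.
    """
    outdir = Path(outdir)
    outputs: dict[str, Path] = {}

    if cfg.counts_csv:
        try:
            logger.info("stage quant: %s", cfg.counts_csv)
            counts, names = read_counts_csv(cfg.counts_csv)
            if counts.empty:
                raise PipelineError("quant: counts table is empty")
            design = read_design_csv(cfg.design_csv) if cfg.design_csv else None
            if design is None:
                raise PipelineError("quant: design_csv is required with counts_csv")
            table = normalize_to_reference(
                SpectralCountTable(counts=counts, design=design, names=names),
                cfg.reference_id,
                cfg.scale,
            )
            summary = trimester_summary(table, ttest_variant=cfg.ttest_variant)
            out = outdir / "summary.csv"
            _write_csv(summary, out, cfg)
            outputs["summary"] = out
            pca = pca_projection(table, scaling=cfg.pca_scaling)
            out = outdir / "pca_scores.csv"
            _write_csv(pca.scores, out, cfg)
            outputs["pca_scores"] = out
            out = outdir / "pca_loadings.csv"
            _write_csv(pca.loadings, out, cfg)
            outputs["pca_loadings"] = out
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"quant: {exc}") from exc

    partitions = None
    if cfg.regions_yml or cfg.fasta or cfg.cleave_fasta or cfg.snp_csv:
        partitions = read_regions_yaml(cfg.regions_yml)

    if cfg.fasta:
        try:
            logger.info("stage regions: %s", cfg.fasta)
            seqs = read_fasta(cfg.fasta)
            ids = list(seqs)
            if len(ids) < 2:
                raise PipelineError("regions: FASTA must hold at least two sequences")
            ref_id = ids[0]
            if ref_id not in partitions:
                raise PipelineError(f"regions: no partition for reference {ref_id!r}")
            aln = global_align(seqs[ids[0]], seqs[ids[1]], level=cfg.level)
            ident = region_identity(aln, partitions[ref_id], cfg.denominator_mode)
            rows = [
                {
                    "region": r.region,
                    "fraction_pct": partitions[ref_id].fraction_pct(r.region)
                    if r.region != "total" else 100.0,
                    "matches": r.matches,
                    "denominator": r.denominator,
                    "identity_pct": round(r.identity_pct, 1),
                    "level": r.level,
                }
                for r in ident.values()
            ]
            out = outdir / "region_identity.csv"
            _write_csv(pd.DataFrame(rows).set_index("region"), out, cfg)
            outputs["region_identity"] = out
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"regions: {exc}") from exc

    if cfg.cleave_fasta:
        try:
            logger.info("stage cleave: %s", cfg.cleave_fasta)
            seqs = read_fasta(cfg.cleave_fasta)
            rules = load_rules(cfg.rules_yml) if cfg.rules_yml else builtin_rules()
            marks, counts = accessibility(seqs, partitions, rules)
            out = outdir / "accessibility.csv"
            _write_csv(marks, out, cfg)
            outputs["accessibility"] = out
            out = outdir / "accessibility_counts.csv"
            _write_csv(counts, out, cfg)
            outputs["accessibility_counts"] = out
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"cleave: {exc}") from exc

    if cfg.phylo_fasta:
        try:
            logger.info("stage phylo: %s", cfg.phylo_fasta)
            seqs = read_fasta(cfg.phylo_fasta)
            labels = list(seqs)
            aligned = progressive_align([seqs[k] for k in labels], level=cfg.level)
            dm = pairwise_distance(labels, aligned, cfg.distance_model)
            out = outdir / "distances.csv"
            _write_csv(dm.to_frame(), out, cfg)
            outputs["distances"] = out
            if cfg.bootstrap_reps > 0:
                tree = bootstrap_support(
                    labels, aligned, n_reps=cfg.bootstrap_reps,
                    seed=cfg.seed, model=cfg.distance_model,
                )
            else:
                tree = nj_tree(dm)
            out = outdir / "tree.nwk"
            _write_text(tree.to_newick(), out, cfg)
            outputs["tree"] = out
            if cfg.bait_columns:
                report = region_vs_whole_report(
                    labels, aligned, cfg.bait_columns, cfg.distance_model
                )
                out = outdir / "bait_vs_whole.csv"
                _write_csv(report, out, cfg, index=False)
                outputs["bait_vs_whole"] = out
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"phylo: {exc}") from exc

    if cfg.snp_csv:
        try:
            logger.info("stage snp: %s", cfg.snp_csv)
            if not cfg.snp_region_id or cfg.snp_region_id not in partitions:
                raise PipelineError("snp: snp_region_id must name a configured partition")
            snps = filter_snps(read_snp_csv(cfg.snp_csv), cfg.maf_min)
            report = region_density(snps, partitions[cfg.snp_region_id], cfg.length_basis)
            out = outdir / "snp_density.csv"
            _write_csv(report, out, cfg)
            outputs["snp_density"] = out
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"snp: {exc}") from exc

    if not outputs:
        raise PipelineError("config enables no stage (no inputs given)")
    return outputs
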