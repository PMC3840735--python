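"""End-to-end analysis pipeline: QC -> distances -> LD -> phase -> Ne -> ROH.

Stages write plain TSV outputs into a run directory and read only the
outputs of their predecessors, so a run is resumable stage by stage and two
runs with the same configuration and inputs produce byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import pandas as pd
import yaml

from snpdemog.errors import UserInputError
from snpdemog.genotype_io import (
    GenotypePanel,
    apply_ld_qc,
    filter_panel,
    read_plink_binary,
    read_plink_text,
    read_recombination_map,
    write_plink_text,
)
from snpdemog.ld_analysis import (
    LDTable,
    chromosome_ld_summary,
    ld_decay_profile,
    pairwise_ld,
)
from snpdemog.ne_estimation import bin_genome, current_ne, past_ne_trajectory
from snpdemog.phase_persistence import phase_correlation, signed_r_catalog
from snpdemog.popgen_stats import (
    allele_sharing_distance,
    combined_distance_table,
    distance_matrix,
    write_phylip,
)
from snpdemog.roh_analysis import (
    ROHParams,
    chromosome_correlation_matrix,
    detect_roh_all,
    summarize_roh,
)
from snpdemog.synthetic_data import make_fixture_suite

logger = logging.getLogger(__name__)

ALL_STAGES = ["qc", "dist", "ld", "phase", "ne", "roh", "report"]
_FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """Serializable pipeline configuration; defaults follow the study's
    published parameter choices."""

    output_dir: Path
    ped: Path | None = None
    map: Path | None = None
    bed: Path | None = None
    bim: Path | None = None
    fam: Path | None = None
    recombination_map: Path | None = None
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    seed: int = 0
    max_missing_fraction: float = 0.05
    maf_min: float = 0.05
    hwe_p_min: float = 0.001
    hwe_test: str = "exact"
    ld_max_distance_bp: int = 3_000_000
    ld_estimator: str = "em"
    phase_bin_bp: int = 100_000
    phase_max_distance_bp: int = 10_000_000
    ne_bin_bp: int = 1_000_000
    ne_c_min: float = 1e-6
    ne_correct_sample_size: bool = False
    plots: bool = False
    roh: ROHParams = field(default_factory=ROHParams)

    def __post_init__(self) -> None:
        for name in ("output_dir", "ped", "map", "bed", "bim", "fam", "recombination_map"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, Path(v))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        roh_raw = raw.pop("roh", {})
        if "mid_class_bp" in roh_raw:
            roh_raw["mid_class_bp"] = tuple(roh_raw["mid_class_bp"])
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(raw) - known
        if unknown:
            raise UserInputError(f"unknown config keys: {sorted(unknown)}")
        for key in ("output_dir", "ped", "map", "bed", "bim", "fam", "recombination_map"):
            if raw.get(key) is not None:
                raw[key] = Path(raw[key])
        if "output_dir" not in raw:
            raise UserInputError("config must set output_dir")
        return cls(roh=ROHParams(**roh_raw), **raw)

    def echo(self) -> dict:
        d = {}
        for name in self.__dataclass_fields__:  # type: ignore[attr-defined]
            v = getattr(self, name)
            if isinstance(v, Path):
                v = str(v)
            elif isinstance(v, ROHParams):
                v = {k: list(x) if isinstance(x, tuple) else x for k, x in vars(v).items()}
            d[name] = v
        return d

    def validate(self) -> None:
        for s in self.stages:
            if s not in ALL_STAGES:
                raise UserInputError(f"unknown stage {s!r}; choose from {ALL_STAGES}")
        if not 0 <= self.max_missing_fraction <= 1:
            raise UserInputError("max_missing_fraction outside [0, 1]")
        if not 0 <= self.maf_min <= 0.5:
            raise UserInputError("maf_min outside [0, 0.5]")
        if not 0 <= self.hwe_p_min <= 1:
            raise UserInputError("hwe_p_min outside [0, 1]")
        for name in ("ld_max_distance_bp", "phase_bin_bp", "phase_max_distance_bp", "ne_bin_bp"):
            if getattr(self, name) <= 0:
                raise UserInputError(f"{name} must be positive")
        if self.ne_c_min < 0:
            raise UserInputError("ne_c_min must be non-negative")


def _read_input_panel(config: RunConfig) -> GenotypePanel:
    if config.ped and config.map:
        return read_plink_text(config.ped, config.map)
    if config.bed and config.bim and config.fam:
        return read_plink_binary(config.bed, config.bim, config.fam)
    raise UserInputError("config must provide ped+map or bed+bim+fam genotype input")


def _read_filtered(outdir: Path) -> GenotypePanel:
    ped = outdir / "qc" / "filtered.ped"
    map_ = outdir / "qc" / "filtered.map"
    if not ped.exists() or not map_.exists():
        raise UserInputError("missing qc outputs; run the qc stage first")
    return read_plink_text(ped, map_)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_qc(config: RunConfig, report: dict) -> None:
    panel = _read_input_panel(config)
    n_in = panel.n_loci
    panel = filter_panel(panel, config.max_missing_fraction)
    out = config.output_dir / "qc"
    out.mkdir(parents=True, exist_ok=True)
    write_plink_text(panel, out / "filtered.ped", out / "filtered.map")
    report["stages"]["qc"] = {
        "loci_in": n_in,
        "loci_out": panel.n_loci,
        "samples": panel.n_samples,
        "populations": panel.populations,
    }


def _stage_dist(config: RunConfig, report: dict) -> None:
    panel = _read_filtered(config.output_dir)
    out = config.output_dir / "dist"
    fst = distance_matrix(panel, "fst")
    nei = distance_matrix(panel, "nei_D")
    combined = combined_distance_table(panel)
    asd = allele_sharing_distance(panel)
    _write_tsv(fst.reset_index(names="population"), out / "fst.tsv")
    _write_tsv(nei.reset_index(names="population"), out / "nei_D.tsv")
    _write_tsv(
        combined.reset_index(names="population"),
        out / "fst_below_nei_above.tsv",
    )
    out.mkdir(parents=True, exist_ok=True)
    write_phylip(asd, out / "asd.phylip")
    report["stages"]["dist"] = {
        "populations": len(fst),
        "samples": len(asd),
    }


def _ld_qc_panels(config: RunConfig, panel: GenotypePanel) -> dict[str, GenotypePanel]:
    return {
        pop: apply_ld_qc(
            panel,
            pop,
            maf_min=config.maf_min,
            hwe_p_min=config.hwe_p_min,
            hwe_test=config.hwe_test,
        )
        for pop in panel.populations
    }


def _stage_ld(config: RunConfig, report: dict) -> None:
    panel = _read_filtered(config.output_dir)
    out = config.output_dir / "ld"
    info = {}
    decay_curves = {}
    for pop, qc_panel in _ld_qc_panels(config, panel).items():
        if qc_panel.n_samples < 3:
            logger.warning("population %s has only %d samples", pop, qc_panel.n_samples)
        ld = pairwise_ld(
            qc_panel,
            max_distance_bp=config.ld_max_distance_bp,
            estimator=config.ld_estimator,
        )
        ld.population = pop
        _write_tsv(ld.table, out / f"{pop}.pairs.tsv")
        if len(ld.table):
            _write_tsv(chromosome_ld_summary(ld), out / f"{pop}.chrom_summary.tsv")
            decay = ld_decay_profile(ld)
            _write_tsv(decay, out / f"{pop}.decay.tsv")
            decay_curves[pop] = decay
        info[pop] = {
            "loci_after_qc": qc_panel.n_loci,
            "n_pairs": len(ld.table),
            "n_failed": ld.n_failed,
        }
    if config.plots and decay_curves:
        from snpdemog.viz import plot_ld_decay

        plot_ld_decay(decay_curves, out / "ld_decay.png")
    report["stages"]["ld"] = info


def _stage_phase(config: RunConfig, report: dict) -> None:
    panel = _read_filtered(config.output_dir)
    out = config.output_dir / "phase"
    catalogs = {}
    for pop, qc_panel in _ld_qc_panels(config, panel).items():
        catalogs[pop] = signed_r_catalog(
            qc_panel,
            max_distance_bp=config.phase_max_distance_bp,
            estimator=config.ld_estimator,
        )
    info = {}
    curves: dict[str, pd.DataFrame] = {}
    for pa, pb in combinations(sorted(catalogs), 2):
        curve = phase_correlation(
            catalogs[pa],
            catalogs[pb],
            bin_width_bp=config.phase_bin_bp,
            max_distance_bp=config.phase_max_distance_bp,
            population_a=pa,
            population_b=pb,
        )
        table = curve.bins.assign(population_a=pa, population_b=pb)
        _write_tsv(table, out / f"{pa}-{pb}.tsv")
        info[f"{pa}-{pb}"] = {"n_shared_pairs": curve.provenance["n_shared_pairs"]}
        curves[f"{pa}-{pb}"] = curve.bins
    if config.plots and curves:
        from snpdemog.viz import plot_phase_curves

        plot_phase_curves(curves, out / "phase_persistence.png")
    report["stages"]["phase"] = info


def _stage_ne(config: RunConfig, report: dict) -> None:
    if config.recombination_map is None:
        raise UserInputError("the ne stage requires a recombination map input")
    rmap = read_recombination_map(config.recombination_map)
    panel = _read_filtered(config.output_dir)
    ld_dir = config.output_dir / "ld"
    out = config.output_dir / "ne"
    rows = []
    info = {}
    trajectories: dict[str, pd.DataFrame] = {}
    for pop in panel.populations:
        pairs_path = ld_dir / f"{pop}.pairs.tsv"
        if not pairs_path.exists():
            raise UserInputError(f"missing LD output {pairs_path}; run the ld stage")
        table = pd.read_csv(pairs_path, sep="\t")
        n_pop = int((panel.samples["population"] == pop).sum())
        if len(table) == 0:
            logger.warning("population %s: no LD pairs; skipped for Ne", pop)
            continue
        ld = LDTable(population=pop, table=table)
        bins = bin_genome(ld, rmap, bin_size_bp=config.ne_bin_bp)
        _write_tsv(bins, out / f"{pop}.bins.tsv")
        est = current_ne(
            bins,
            sample_size=n_pop,
            correct_sample_size=config.ne_correct_sample_size,
        )
        rows.append((pop, n_pop, est.mean_ne, est.sd_ne, est.n_bins))
        traj = past_ne_trajectory(bins, c_min=config.ne_c_min)
        _write_tsv(traj, out / f"{pop}.trajectory.tsv")
        trajectories[pop] = traj
        info[pop] = {"n_bins": est.n_bins, "mean_ne": est.mean_ne}
    if config.plots and trajectories:
        from snpdemog.viz import plot_ne_trajectory

        plot_ne_trajectory(trajectories, out / "ne_trajectory.png")
    if rows:
        _write_tsv(
            pd.DataFrame(rows, columns=["population", "n", "mean_ne", "sd_ne", "n_bins"]),
            out / "current_ne.tsv",
        )
    report["stages"]["ne"] = info


def _stage_roh(config: RunConfig, report: dict) -> None:
    panel = _read_filtered(config.output_dir)
    out = config.output_dir / "roh"
    rohs = detect_roh_all(panel, config.roh)
    _write_tsv(rohs, out / "roh.tsv")
    summary = summarize_roh(rohs, panel, config.roh)
    _write_tsv(summary.per_sample, out / "per_sample.tsv")
    _write_tsv(summary.per_population, out / "per_population.tsv")
    info = {
        "n_roh": len(rohs),
        "covered_genome_bp": summary.covered_genome_bp,
    }
    # chromosome-level correlation of LD, ROH length and recombination rate
    ld_dir = config.output_dir / "ld"
    summaries = sorted(ld_dir.glob("*.chrom_summary.tsv"))
    if summaries and config.recombination_map is not None and len(rohs):
        frames = [pd.read_csv(p, sep="\t", dtype={"chromosome": str}) for p in summaries]
        pooled = (
            pd.concat(frames)
            .query("chromosome != 'Total'")
            .groupby("chromosome", as_index=False)["mean_r2"]
            .mean()
        )
        rmap = read_recombination_map(config.recombination_map)
        try:
            rho, pval = chromosome_correlation_matrix(pooled, rohs, rmap)
            _write_tsv(rho.reset_index(names="variable"), out / "correlation_rho.tsv")
            _write_tsv(pval.reset_index(names="variable"), out / "correlation_p.tsv")
            info["correlations"] = {
                "ld_vs_roh_length": float(rho.loc["mean_r2", "mean_roh_length_bp"]),
                "roh_length_vs_rate": float(
                    rho.loc["mean_roh_length_bp", "rate_cm_per_mb"]
                ),
            }
        except UserInputError as exc:
            logger.warning("correlation matrix skipped: %s", exc)
    report["stages"]["roh"] = info


def _stage_report(config: RunConfig, report: dict) -> None:
    out = config.output_dir
    manifest = {}
    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name not in ("run_report.json", "report.md"):
            manifest[str(path.relative_to(out))] = _sha256(path)
    report["files"] = manifest
    lines = ["# Run report", "", "## Stages", ""]
    for stage, data in report["stages"].items():
        lines.append(f"### {stage}")
        lines.append("```json")
        lines.append(json.dumps(data, indent=1, sort_keys=True, default=str))
        lines.append("```")
        lines.append("")
    lines.append("## Files")
    lines.append("")
    for name, digest in manifest.items():
        lines.append(f"- `{name}` sha256 `{digest[:16]}`")
    lines.append("")
    (out / "report.md").write_text("\n".join(lines))


_STAGE_FUNCS = {
    "qc": _stage_qc,
    "dist": _stage_dist,
    "ld": _stage_ld,
    "phase": _stage_phase,
    "ne": _stage_ne,
    "roh": _stage_roh,
    "report": _stage_report,
}


def run_pipeline(config: RunConfig, stages: list[str] | None = None) -> dict:
    """Execute the enabled stages in dependency order and return the report.

    The report (also written to ``run_report.json``) echoes the full
    configuration, per-stage record counts and a checksummed file manifest.
    A stage failure aborts the run with the stage name in the error message.
    """
    config.validate()
    stages = [s for s in ALL_STAGES if s in (stages or config.stages)]
    config.output_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": config.echo(), "stages": {}}
    for stage in stages:
        try:
            _STAGE_FUNCS[stage](config, report)
        except UserInputError:
            raise
        except Exception as exc:  # pragma: no cover - defensive
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    (config.output_dir / "run_report.json").write_text(
        json.dumps(report, indent=1, sort_keys=True, default=str)
    )
    return report


def simulate_fixtures(out_dir: str | Path, seed: int) -> dict:
    """Write the synthetic fixture suite (thin wrapper for the CLI)."""
    return make_fixture_suite(out_dir, seed)
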