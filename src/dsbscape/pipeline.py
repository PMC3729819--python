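"""End-to-end orchestration: simulate -> filter -> call -> scan -> classify -> landscape.

A run is fully specified by a RunConfig (YAML-serializable flat config)
and a seed; two runs with the same config and seed produce identical
reports. Each stage writes its intermediate files under the output
directory so the record counts flowing through the quality and duplicate
filters are auditable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as dio
from .errors import StageError, UndefinedResultError
from .fragments import FilterParams, apply_filters, pool_replicates
from .hotspots import CallerParams, call_hotspots
from .landscape import (
    ParDefinition,
    in_hotspot_window_profile,
    par_cluster_fraction,
    subtelomere_depletion_stat,
)
from .motifs import scan_consensus
from .overlaps import (
    OverlapParams,
    classification_summary,
    classify_hotspots,
    strength_correlation,
)
from .simulate import (
    ConditionParams,
    ParSpec,
    SimConfig,
    generate_genome,
    simulate_fragments,
    simulate_h3k4me3_tags,
)

__version__ = "0.1.0"

log = logging.getLogger("dsbscape")


def default_conditions(sim: SimConfig) -> list[ConditionParams]:
    """Four study-style conditions sharing one planted truth set.

    The reference condition (wild-type-like) lacks Gal4-targeted
    hotspots; the knockout-like condition is a low-depth replica of it;
    the two Gal-targeting conditions activate Gal4-flagged hotspots,
    suppress subtelomeric hotspot strength and nearly silence the PAR
    cluster. Efficiencies echo the relative sequencing depths of the
    four samples the report emulates.
    """
    return [
        ConditionParams(name="wildtype_like", efficiency=1.0, gal4_factor=0.0),
        ConditionParams(name="hop2_like", efficiency=0.25, gal4_factor=0.0),
        ConditionParams(
            name="gal_like",
            efficiency=0.5,
            gal4_factor=1.0,
            subtelomere_factor=sim.subtelomere_factor,
            par_factor=0.03,
        ),
        ConditionParams(
            name="gal_hop2_like",
            efficiency=1.0,
            gal4_factor=1.0,
            subtelomere_factor=sim.subtelomere_factor,
            par_factor=0.03,
        ),
    ]


@dataclass
class RunConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    conditions: list[ConditionParams] | None = None
    filters: FilterParams = field(default_factory=FilterParams)
    caller: CallerParams = field(default_factory=CallerParams)
    overlap: OverlapParams = field(default_factory=OverlapParams)
    landscape_bin: int = 1_000_000
    end_mask: int = 3_000_000
    end_width: int = 5_000_000
    n_permutations: int = 1_000
    n_replicates: int = 2
    reference_condition: str = "wildtype_like"
    seed: int = 0
    outdir: str = "dsbscape_run"
    write_genome: bool = True

    def resolved_conditions(self) -> list[ConditionParams]:
        return self.conditions or default_conditions(self.sim)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["conditions"] = [
            dataclasses.asdict(c) for c in self.resolved_conditions()
        ]
        return d

    def config_hash(self) -> str:
        """Hash of the analysis parameters (output location excluded)."""
        d = self.to_dict()
        d.pop("outdir", None)
        d.pop("write_genome", None)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "sim" in d:
            sim = dict(d["sim"])
            if "par" in sim and isinstance(sim["par"], dict):
                sim["par"] = ParSpec(**sim["par"])
            d["sim"] = SimConfig(**sim)
        if d.get("conditions"):
            d["conditions"] = [ConditionParams(**c) for c in d["conditions"]]
        if "filters" in d:
            d["filters"] = FilterParams(**d["filters"])
        if "caller" in d:
            d["caller"] = CallerParams(**d["caller"])
        if "overlap" in d:
            d["overlap"] = OverlapParams(**d["overlap"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class RunReport:
    """Machine-readable summary of one pipeline run."""

    rows: list[dict]                # Table-1-style per-condition rows
    landscape: dict                 # per-condition depletion stats
    par: dict                       # per-condition PAR fractions
    correlations: dict              # log-strength Spearman vs reference
    version: str
    config_hash: str
    seed: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunReport":
        with open(path) as fh:
            return cls(**json.load(fh))


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.time()
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - rewrap with stage name
                raise StageError(name, str(exc)) from exc
            log.info("stage %s: done in %.1fs", name, time.time() - t0)
            return out
        return wrapped
    return deco


def _derive_seed(base: int, k: int) -> int:
    return (base * 1_000_003 + k) % (2**31)


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute every stage in fixed order and emit the RunReport.

    Stages: genome+truth simulation, motif scan, per-condition fragment
    simulation (n_replicates each) -> quality filter -> duplicate cap ->
    pooling -> hotspot calling, H3K4me3 simulation, overlap
    classification against the reference condition's hotspots, landscape
    profiling with the subtelomeric depletion statistic, and the PAR
    fraction. All intermediates are written under ``config.outdir``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = config.sim
    conditions = config.resolved_conditions()
    chrom_lengths = dict(sim.chrom_lengths)

    genome, truth = _stage("simulate_genome")(generate_genome)(sim)
    dio.write_truth(truth, outdir)
    if config.write_genome:
        dio.write_fasta(genome, outdir / "genome.fa")

    sites = _stage("motif_scan")(scan_consensus)(genome)
    dio.write_bed(sites, outdir / "gal4_sites.bed")
    log.info("motif scan: %d consensus sites", len(sites))

    pooled: dict[str, pd.DataFrame] = {}
    called: dict[str, pd.DataFrame] = {}
    tags: dict[str, pd.DataFrame] = {}
    h3k4_peaks = None

    @_stage("fragments")
    def _make_fragments(cond: ConditionParams, idx: int) -> pd.DataFrame:
        reps = []
        for r in range(config.n_replicates):
            frags, book = simulate_fragments(
                sim, truth, cond,
                seed=_derive_seed(config.seed, 100 * idx + r),
                replicate=f"rep{r + 1}",
            )
            log.info(
                "%s rep%d: %d emitted (%d distinct, %d background)",
                cond.name, r + 1, book["n_emitted"], book["n_distinct"],
                book["n_background"],
            )
            filtered = apply_filters(frags, config.filters)
            log.info(
                "%s rep%d: %d after quality filter + duplicate cap",
                cond.name, r + 1, len(filtered),
            )
            reps.append(filtered)
        pool = pool_replicates(reps, chrom_lengths)
        dio.write_fragments(pool, outdir / f"fragments_{cond.name}.bed")
        return pool

    for idx, cond in enumerate(conditions):
        pooled[cond.name] = _make_fragments(cond, idx)
        called[cond.name] = _stage("call_hotspots")(call_hotspots)(
            pooled[cond.name], chrom_lengths, config.caller
        )
        dio.write_hotspots(called[cond.name], outdir / f"hotspots_{cond.name}.bed")
        log.info("%s: %d hotspots", cond.name, len(called[cond.name]))
        t, peaks = _stage("h3k4me3")(simulate_h3k4me3_tags)(
            truth, seed=_derive_seed(config.seed, 900 + idx)
        )
        tags[cond.name] = t
        if h3k4_peaks is None:
            h3k4_peaks = peaks
            dio.write_bed(peaks, outdir / "h3k4me3_peaks.bed")

    ref_name = config.reference_condition
    if ref_name not in called:
        raise StageError("classify", f"unknown reference condition {ref_name!r}")
    reference = called[ref_name]

    rows, correlations = [], {}
    for cond in conditions:
        hs = called[cond.name]
        classified = _stage("classify")(classify_hotspots)(
            hs,
            reference=reference if cond.name != ref_name else reference,
            motifs=sites,
            h3k4me3=h3k4_peaks,
            params=config.overlap,
            chrom_lengths=chrom_lengths,
        )
        classified.to_csv(
            outdir / f"classification_{cond.name}.tsv", sep="\t", index=False
        )
        summary = classification_summary(classified)
        summary["condition"] = cond.name
        summary["n_fragments"] = len(pooled[cond.name])
        rows.append(summary)
        if cond.name != ref_name and len(hs) and len(reference):
            try:
                correlations[cond.name] = strength_correlation(
                    hs, reference, config.overlap, chrom_lengths
                )
            except UndefinedResultError:
                correlations[cond.name] = None

    landscape: dict = {}
    par: dict = {}
    regions = reference[["chrom", "start", "end"]]
    if len(regions):
        ref_profile = in_hotspot_window_profile(
            pooled[ref_name], regions, chrom_lengths,
            bin=config.landscape_bin, end_mask=config.end_mask,
        )
        ref_tag_profile = in_hotspot_window_profile(
            tags[ref_name], regions, chrom_lengths,
            bin=config.landscape_bin, end_mask=config.end_mask,
        )
        for cond in conditions:
            if cond.name == ref_name:
                continue
            entry: dict = {}
            try:
                prof = in_hotspot_window_profile(
                    pooled[cond.name], regions, chrom_lengths,
                    bin=config.landscape_bin, end_mask=config.end_mask,
                )
                dio.write_profile(prof, outdir / f"profile_dsb_{cond.name}.tsv")
                R, p = subtelomere_depletion_stat(
                    prof, ref_profile, config.end_width,
                    config.n_permutations, seed=_derive_seed(config.seed, 7),
                )
                entry["dsb"] = {"R": R, "p": p}
                tag_prof = in_hotspot_window_profile(
                    tags[cond.name], regions, chrom_lengths,
                    bin=config.landscape_bin, end_mask=config.end_mask,
                )
                Rt, pt = subtelomere_depletion_stat(
                    tag_prof, ref_tag_profile, config.end_width,
                    config.n_permutations, seed=_derive_seed(config.seed, 8),
                )
                entry["h3k4me3"] = {"R": Rt, "p": pt}
            except UndefinedResultError as exc:
                entry["error"] = str(exc)
            landscape[cond.name] = entry
    if sim.par is not None:
        par_def = ParDefinition(
            sim.par.chrom, sim.par.start, sim.par.start + sim.par.width
        )
        for cond in conditions:
            if len(pooled[cond.name]):
                par[cond.name] = par_cluster_fraction(pooled[cond.name], par_def)

    report = RunReport(
        rows=rows,
        landscape=landscape,
        par=par,
        correlations=correlations,
        version=__version__,
        config_hash=config.config_hash(),
        seed=config.seed,
    )
    report.to_json(outdir / "report.json")
    with open(outdir / "table1.txt", "w") as fh:
        fh.write(format_table1(report) + "\n")
    config.to_yaml(outdir / "config_used.yaml")
    return report


def _fmt_pct(p: float | None) -> str:
    if p is None:
        return "(—)"
    if p == 100:
        return "(100%)"
    return f"({p:.1f}%)"


def format_table1(report: RunReport) -> str:
    """Render the per-condition summary as a fixed-format text table.

    Counts carry thousands separators; percentages sit in parentheses to
    one decimal (100% shown without a decimal); empty categories render
    an em dash.
    """
    header = (
        "Sample\tFragments\tIdentified hotspots\t"
        "Hotspots with Gal4 consensus\tHotspots present in the reference"
    )
    lines = [header]
    for row in report.rows:
        n = row["n_hotspots"]
        if n == 0:
            lines.append(f"{row['condition']}\t{row['n_fragments']:,}\t0\t0 (—)\t0 (—)")
            continue
        lines.append(
            f"{row['condition']}\t{row['n_fragments']:,}\t{n:,}\t"
            f"{row['n_motif']:,} {_fmt_pct(row['pct_motif'])}\t"
            f"{row['n_shared']:,} {_fmt_pct(row['pct_shared'])}"
        )
    return "\n".join(lines)


def format_table1_row(n_hotspots: int, n_motif: int, n_shared: int) -> str:
    """One row of the summary table from raw counts (worked-example form)."""
    from .intervals import percent

    if n_hotspots == 0:
        return "0  0 (—)  0 (—)"
    return (
        f"{n_hotspots:,}  {n_motif:,} {_fmt_pct(percent(n_motif, n_hotspots))}  "
        f"{n_shared:,} {_fmt_pct(percent(n_shared, n_hotspots))}"
    )
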