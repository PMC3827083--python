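"""End-to-end orchestration: simulate -> normalize -> detect -> DE ->
concordance -> cluster, plus the standalone probe-thermodynamics report.

The run configuration is a strict YAML schema (unknown keys rejected). All
randomness flows from the single configured seed; running the same
configuration twice produces byte-identical output files. Every stage appends
to a plain-text provenance log sufficient to re-run it in isolation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from mirxplat import concordance as conc
from mirxplat import diffexp
from mirxplat.cluster import ClusterTree, export_tree, hca
from mirxplat.hybrid_thermo import (
    NearestNeighborTable,
    ThermoConditions,
    ThermoError,
    probe_variants,
)
from mirxplat.normalize import (
    ExpressionMatrix,
    clamp_negatives,
    percentile_scale,
    quantile_normalize,
    summarize_replicates,
)
from mirxplat.seqlib import ProbeRecord, SequenceRecord, gc_content, load_probe_panel, read_sequences
from mirxplat.synthetic_data import GROUPS, PlatformBias, SimulationConfig, simulate_qpcr, simulate_two_platforms


class ConfigError(ValueError):
    pass


CONTRASTS = {"M": ("M_cRaf", "M_WT"), "F": ("F_cRaf", "F_WT")}


@dataclass(frozen=True)
class DetectionSettings:
    rule: str = "median_above_threshold"
    threshold: float | None = None


@dataclass(frozen=True)
class DESettings:
    p_max: float = 0.05
    min_abs_log2fc: float = 1.5
    min_mean_percentile: float = 50.0
    min_linear_fc: float | None = None
    use_log2_for_test: bool = True


@dataclass(frozen=True)
class RunConfig:
    """Validated pipeline configuration."""

    simulation: SimulationConfig
    detection: DetectionSettings = DetectionSettings()
    de: DESettings = DESettings()
    output_dir: Path = Path("mirxplat_out")
    universe_file: Path | None = None
    seed: int = 0

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any], base_dir: Path | None = None) -> "RunConfig":
        known = {"simulation", "detection", "de", "output_dir", "universe_file", "seed"}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        seed = int(raw.get("seed", 0))

        sim_raw = dict(raw.get("simulation", {}))
        sim_fields = {f.name for f in dataclasses.fields(SimulationConfig)}
        unknown = set(sim_raw) - sim_fields
        if unknown:
            raise ConfigError(f"unknown simulation keys: {sorted(unknown)}")
        for key in ("platform_bias_a", "platform_bias_b"):
            if key in sim_raw:
                sim_raw[key] = PlatformBias(**sim_raw[key])
        if "planted_effects" in sim_raw:
            sim_raw["planted_effects"] = {
                k: (float(v[0]), v[1]) for k, v in sim_raw["planted_effects"].items()
            }
        sim_raw.setdefault("seed", seed)
        simulation = SimulationConfig(**sim_raw)

        def section(name: str, klass):
            sec = dict(raw.get(name, {}))
            fields = {f.name for f in dataclasses.fields(klass)}
            unknown = set(sec) - fields
            if unknown:
                raise ConfigError(f"unknown {name} keys: {sorted(unknown)}")
            return klass(**sec)

        base = base_dir or Path.cwd()
        universe = raw.get("universe_file")
        universe_path = None
        if universe is not None:
            universe_path = (base / universe) if not Path(universe).is_absolute() else Path(universe)
            if not universe_path.exists():
                raise ConfigError(f"universe file not found: {universe_path}")
        out = raw.get("output_dir", "mirxplat_out")
        out_path = (base / out) if not Path(out).is_absolute() else Path(out)
        return cls(
            simulation=simulation,
            detection=section("detection", DetectionSettings),
            de=section("de", DESettings),
            output_dir=out_path,
            universe_file=universe_path,
            seed=seed,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        """Load and validate a YAML run configuration.

        Relative ``output_dir`` / ``universe_file`` paths resolve against the
        directory containing the config file.
        """
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_dict(raw, base_dir=path.parent)


@dataclass
class PipelineResult:
    """In-memory bundle of every stage output plus the provenance log."""

    config: RunConfig
    matrix_a: ExpressionMatrix
    matrix_b: ExpressionMatrix
    truth: Any
    de_tables: dict[str, dict[str, pd.DataFrame]]  # platform -> sex -> full DE table
    significant: dict[str, dict[str, pd.DataFrame]]
    detection_overlap: dict[str, conc.ConcordanceSummary]
    de_overlap: conc.ConcordanceSummary | None
    gc_report: conc.GCDiscordanceReport | None
    tree: ClusterTree | None
    qpcr: pd.DataFrame
    provenance: list[str]
    output_dir: Path


def _de_layout(tables: dict[str, pd.DataFrame], significant: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Combined per-platform DE table: one row per miRNA, per-sex columns."""
    out = pd.DataFrame(index=tables["F"].index)
    out.index.name = "mirna"
    for sex in ("F", "M"):
        out[f"p_{sex}"] = tables[sex]["p"]
        out[f"log2_{sex}"] = tables[sex]["log2_ratio"]
    for sex in ("F", "M"):
        out[f"significant_{sex}"] = out.index.isin(significant[sex].index)
    return out


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Execute the full simulated two-platform analysis and write all outputs."""
    prov: list[str] = [f"run_pipeline seed={cfg.seed}"]
    outdir = cfg.output_dir
    outdir.mkdir(parents=True, exist_ok=True)

    # stage: simulate
    mat_a_raw, mat_b_raw, truth = simulate_two_platforms(cfg.simulation)
    qpcr = simulate_qpcr(cfg.simulation, truth)
    prov += mat_a_raw.log + mat_b_raw.log + [f"simulate_qpcr shape={qpcr.shape}"]

    universe = list(truth.true_log2fc.index)
    if cfg.universe_file is not None:
        universe = [ln.strip() for ln in cfg.universe_file.read_text().splitlines() if ln.strip()]
        prov.append(f"universe_file={cfg.universe_file} n={len(universe)}")

    # stage: normalize (platform A: quantile; platform B: percentile -> clamp -> median)
    mat_a = quantile_normalize(mat_a_raw)
    mat_b = summarize_replicates(clamp_negatives(percentile_scale(mat_b_raw)))
    prov += mat_a.log[-1:] + mat_b.log[-3:]

    # stage: detection + overlap per group
    calls_a = conc.call_detected(mat_a, cfg.detection.rule, cfg.detection.threshold)
    calls_b = conc.call_detected(mat_b, cfg.detection.rule, cfg.detection.threshold)
    prov += [f"call_detected platform=A {calls_a.rule}", f"call_detected platform=B {calls_b.rule}"]
    detection_overlap = {
        group: conc.overlap_stats(
            calls_a.detected_in(group) & set(universe),
            calls_b.detected_in(group) & set(universe),
            universe,
        )
        for group in cfg.simulation.groups
    }

    # stage: differential expression per platform arm and sex
    de_tables: dict[str, dict[str, pd.DataFrame]] = {}
    significant: dict[str, dict[str, pd.DataFrame]] = {}
    for platform, mat in (("A", mat_a), ("B", mat_b)):
        de_tables[platform] = {}
        significant[platform] = {}
        for sex, contrast in CONTRASTS.items():
            table = diffexp.de_table(mat, contrast, use_log2_for_test=cfg.de.use_log2_for_test)
            sig = diffexp.filter_significant(
                table,
                p_max=cfg.de.p_max,
                min_abs_log2fc=cfg.de.min_abs_log2fc,
                min_mean_percentile=cfg.de.min_mean_percentile,
                min_linear_fc=cfg.de.min_linear_fc,
            )
            de_tables[platform][sex] = table
            significant[platform][sex] = sig
            prov.append(
                f"de_table platform={platform} contrast={contrast} "
                f"n_significant={len(sig)} filter={sig.attrs.get('filter')}"
            )

    sig_a = set().union(*(significant["A"][s].index for s in CONTRASTS))
    sig_b = set().union(*(significant["B"][s].index for s in CONTRASTS))
    de_overlap = conc.overlap_stats(sig_a & set(universe), sig_b & set(universe), universe)
    gc_report = conc.gc_discordance(sig_a, sig_b, truth.gc.to_dict())
    prov.append(f"de_overlap common={len(de_overlap.common)} A-only={len(de_overlap.only_a)} B-only={len(de_overlap.only_b)}")

    # stage: clustering of per-arm, per-sex log2-ratio profiles
    tree = None
    union = sorted(sig_a | sig_b)
    if len(union) >= 2:
        profiles = pd.DataFrame(
            {
                f"{platform}_{sex}": de_tables[platform][sex]["log2_ratio"]
                for platform in ("A", "B")
                for sex in ("M", "F")
            }
        ).loc[union]
        profiles = profiles[profiles.std(axis=1) > 0]
        if len(profiles) >= 2:
            tree = hca(profiles, linkage="average")
            prov.append(f"hca n_leaves={len(profiles)} linkage=average")

    # stage: write outputs
    mat_a.values.to_csv(outdir / "platformA_normalized.tsv", sep="\t")
    mat_b.values.to_csv(outdir / "platformB_summarized.tsv", sep="\t")
    qpcr.to_csv(outdir / "qpcr_ct.tsv", sep="\t", index=False)
    truth.true_log2fc.to_csv(outdir / "ground_truth_log2fc.tsv", sep="\t")
    for platform in ("A", "B"):
        _de_layout(de_tables[platform], significant[platform]).to_csv(
            outdir / f"de_platform{platform}.tsv", sep="\t"
        )
    summary = {
        "detection_by_group": {g: s.to_dict() for g, s in detection_overlap.items()},
        "significant_overlap": de_overlap.to_dict(),
        "gc_discordance": gc_report.to_dict(),
    }
    (outdir / "concordance.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    if tree is not None:
        (outdir / "cluster.nwk").write_text(export_tree(tree) + "\n")
        tree.merge_table().to_csv(outdir / "cluster_merges.tsv", sep="\t", index=False)
    (outdir / "provenance.log").write_text("\n".join(prov) + "\n")

    return PipelineResult(
        config=cfg,
        matrix_a=mat_a,
        matrix_b=mat_b,
        truth=truth,
        de_tables=de_tables,
        significant=significant,
        detection_overlap=detection_overlap,
        de_overlap=de_overlap,
        gc_report=gc_report,
        tree=tree,
        qpcr=qpcr,
        provenance=prov,
        output_dir=outdir,
    )


def thermo_report(
    mirnas: Sequence[SequenceRecord],
    probes: Sequence[tuple[str, ProbeRecord]],
    cond: ThermoConditions | None = None,
    nn: NearestNeighborTable | None = None,
) -> pd.DataFrame:
    """Per-probe GC / free-energy / Tm table.

    ``probes`` pairs each probe with the name of its target miRNA. Probes with
    an optional 3' residue produce two rows (tail-bearing variant first).
    Pairing failures are flagged per row; the run continues.
    """
    nn = nn or NearestNeighborTable.default()
    cond = cond or ThermoConditions()
    by_name = {m.name: m for m in mirnas}
    rows = []
    for target, probe in probes:
        rna = by_name.get(target)
        if rna is None:
            rows.append({"mirna": target, "probe": str(probe), "variant": "", "gc_pct": None,
                         "dG37_kcal": None, "tm_C": None, "status": "error: unknown miRNA"})
            continue
        gc = gc_content(rna)
        try:
            results = probe_variants(rna, probe, nn, cond)
        except ThermoError as exc:
            rows.append({"mirna": target, "probe": str(probe), "variant": "", "gc_pct": gc,
                         "dG37_kcal": None, "tm_C": None, "status": f"error: {exc}"})
            continue
        labels = ["with_tail", "base"] if len(results) == 2 else ["single"]
        for label, res in zip(labels, results):
            rows.append({"mirna": target, "probe": res.probe_seq, "variant": label, "gc_pct": gc,
                         "dG37_kcal": round(res.dG37, 1), "tm_C": round(res.tm, 1), "status": "ok"})
    return pd.DataFrame(rows)


def panel_thermo_report(cond: ThermoConditions | None = None) -> pd.DataFrame:
    """Thermodynamics report for the packaged 12-assay probe panel."""
    panel = load_probe_panel()
    mirnas = [e.mirna for e in panel]
    rows = []
    for platform, pick in (("Agilent", lambda e: e.agilent_probe), ("Affymetrix", lambda e: e.affymetrix_probe)):
        report = thermo_report(mirnas, [(e.mirna.name, pick(e)) for e in panel], cond)
        report.insert(0, "platform", platform)
        rows.append(report)
    return pd.concat(rows, ignore_index=True)
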