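"""End-to-end orchestration: simulate -> trace -> measure -> stats.

A single run config drives replicated experiments over one or more
conditions (e.g. oxidising vs reducing), with every random stage seeded
deterministically from one master seed, and produces the per-condition
summary table (occupancy per DNA +/- SD, specificity S +/- SD,
significance stars against a reference condition) plus a machine-
readable JSON report.  Re-running with the same config and seed
reproduces every output byte for byte.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .complexes import measure_traces
from .core import InvalidConfigError, validate_measurements
from .io import write_measurements
from .stats import (build_position_histogram, compare_replicates,
                    decompose_bend_states, fit_position_model,
                    occupancy_at_site, specificity_from_fit)
from .synthetic import GeneratorConfig, emit_measurement_table, generate_scene
from .tracing import QC_OK, trace_height_map

__all__ = ["RunConfig", "run_all"]


@dataclass
class RunConfig:
    """Declarative description of one replicated pipeline run."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    conditions: dict = field(default_factory=lambda: {"reducing": {}})
    reference_condition: str | None = None
    replicates: int = 3
    mode: str = "tabular"            # "tabular" or "image"
    site_pct: float = 49.8
    n_sites: int = 505
    bend_k: int = 3
    bend_init_means: tuple = (0.0, 35.0, 70.0)
    length_tolerance: float = 0.2

    def __post_init__(self) -> None:
        if self.mode not in ("tabular", "image"):
            raise InvalidConfigError("mode must be 'tabular' or 'image'")
        if self.replicates < 1:
            raise InvalidConfigError("need at least one replicate")
        if self.reference_condition is None:
            self.reference_condition = next(iter(self.conditions))
        if self.reference_condition not in self.conditions:
            raise InvalidConfigError("reference condition not in conditions")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        gen = d.pop("generator", {})
        return cls(generator=GeneratorConfig(**gen), **d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("conditions", "reference_condition", "replicates", "mode",
              "site_pct", "n_sites", "bend_k", "bend_init_means",
              "length_tolerance")}
        d["generator"] = self.generator.to_dict()
        return d


def _config_hash(config: RunConfig) -> str:
    canonical = yaml.safe_dump(json.loads(json.dumps(config.to_dict())),
                               sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def _run_replicate(gen_cfg: GeneratorConfig, mode: str,
                   rng: np.random.Generator, run_cfg: RunConfig):
    """One deposition/imaging replicate -> (measurements, n_dna, qc rows)."""
    if mode == "tabular":
        df = emit_measurement_table(gen_cfg, rng)
        return df, gen_cfg.n_molecules, []
    scene = generate_scene(gen_cfg, rng, on_offgrid="skip")
    traces = trace_height_map(
        scene.height_map,
        expected_length_nm=gen_cfg.contour_length_nm,
        tolerance_fraction=run_cfg.length_tolerance)
    df, n_dna = measure_traces(scene.height_map, traces,
                               condition=gen_cfg.condition,
                               replicate=gen_cfg.replicate)
    qc_rows = [{"condition": gen_cfg.condition,
                "replicate": gen_cfg.replicate,
                "molecule_id": t.molecule_label,
                "qc_status": t.qc_status}
               for t in traces if t.qc_status != QC_OK]
    return df, n_dna, qc_rows


def run_all(config: RunConfig, seed: int, outdir) -> dict:
    """Execute every stage for every condition and replicate.

    Writes per-replicate measurement CSVs, a Table-style summary CSV, a
    QC reject log and a JSON run report; returns the report dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    report: dict = {
        "config_hash": _config_hash(config),
        "master_seed": int(seed),
        "version": __version__,
        "mode": config.mode,
        "conditions": {},
    }
    per_condition: dict = {}
    qc_log: list[dict] = []
    conditions = list(config.conditions)
    children = ss.spawn(len(conditions) * config.replicates)

    for ci, cond in enumerate(conditions):
        frames, n_dna_map, s_values = [], {}, []
        for ri in range(config.replicates):
            rep = f"r{ri + 1}"
            child = children[ci * config.replicates + ri]
            rng = np.random.default_rng(child)
            gen_cfg = config.generator.with_(
                condition=cond, replicate=rep,
                **config.conditions[cond])
            try:
                df, n_dna, qc = _run_replicate(gen_cfg, config.mode, rng,
                                               config)
            except Exception as exc:
                raise RuntimeError(
                    f"stage failed for condition {cond!r} replicate {rep!r} "
                    f"after {sum(len(f) for f in frames)} measured "
                    f"complexes: {exc}") from exc
            validate_measurements(df)
            frames.append(df)
            n_dna_map[rep] = n_dna
            qc_log.extend(qc)
            write_measurements(
                df, outdir / f"measurements_{cond}_{rep}.csv")
            # per-replicate specificity for the SD over replicates
            if len(df):
                hist_r = build_position_histogram(df, 2.0, n_dna)
                fit_r = fit_position_model(hist_r, config.site_pct)
                if fit_r.success and fit_r.background_level > 0:
                    spec_r = specificity_from_fit(fit_r, hist_r,
                                                  config.n_sites)
                    s_values.append(spec_r.S)

        all_df = pd.concat(frames, ignore_index=True) if frames else \
            pd.DataFrame()
        occ_mean, occ_sd, occ_per_rep = occupancy_at_site(all_df, n_dna_map)
        n_dna_total = int(sum(n_dna_map.values()))
        hist = build_position_histogram(all_df, 2.0, n_dna_total)
        fit = fit_position_model(hist, config.site_pct)
        spec = None
        if fit.success and fit.background_level > 0:
            spec = specificity_from_fit(
                fit, hist, config.n_sites,
                sd_over_replicates=(float(np.std(s_values, ddof=1))
                                    if len(s_values) > 1 else None))
        angles = all_df["bend_angle_deg"].dropna().to_numpy() \
            if len(all_df) else np.empty(0)
        bend = None
        if len(angles) >= 30:
            bend = decompose_bend_states(angles, config.bend_k,
                                         config.bend_init_means)
        per_condition[cond] = {
            "n_dna": n_dna_total,
            "n_complexes": int(len(all_df)),
            "occupancy_mean": occ_mean,
            "occupancy_sd": occ_sd,
            "occupancy_per_replicate": occ_per_rep,
            "S": None if spec is None else spec.S,
            "S_sd": None if spec is None else spec.sd_over_replicates,
            "position_center_pct": fit.components[0][0]
            if fit.components else None,
            "bend_state_means": None if bend is None else
            [c[0] for c in bend.components],
        }

    # significance of each condition's occupancy against the reference
    ref = config.reference_condition
    ref_vals = list(per_condition[ref]["occupancy_per_replicate"].values())
    rows = []
    for cond in conditions:
        entry = per_condition[cond]
        vals = list(entry["occupancy_per_replicate"].values())
        if cond != ref and len(vals) == 3 and len(ref_vals) == 3:
            cmp_res = compare_replicates(vals, ref_vals)
            t_stat, p, stars = (cmp_res.t_statistic, cmp_res.p_value,
                                cmp_res.stars)
        else:
            t_stat = p = None
            stars = "ref" if cond == ref else "n/a"
        entry["t_vs_reference"] = t_stat
        entry["p_vs_reference"] = p
        entry["stars"] = stars
        rows.append({
            "condition": cond,
            "n_replicates": config.replicates,
            "n_dna": entry["n_dna"],
            "n_complexes": entry["n_complexes"],
            "occupancy_per_dna": entry["occupancy_mean"],
            "occupancy_sd": entry["occupancy_sd"],
            "specificity_S": entry["S"],
            "specificity_sd": entry["S_sd"],
            "t_vs_reference": t_stat,
            "p_vs_reference": p,
            "significance": stars,
        })
        report["conditions"][cond] = entry

    summary = pd.DataFrame(rows)
    summary.to_csv(outdir / "summary.csv", index=False, float_format="%.6g")
    pd.DataFrame(qc_log, columns=["condition", "replicate", "molecule_id",
                                  "qc_status"]).to_csv(
        outdir / "qc_rejects.csv", index=False)
    (outdir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, default=float))
    return report
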