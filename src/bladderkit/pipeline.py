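"""End-to-end orchestration: synthesis -> morphometrics -> FEM -> ephys -> stats.

``run_pipeline`` executes the whole analysis on synthetic data and writes
every table, a JSON manifest sufficient to re-run the pipeline
bit-identically, and summary figures (morphospace, tuning curves, FRF,
per-angle power difference).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, ephys, fem, morphometrics as morph, stats, synthetic

log = logging.getLogger("bladderkit")

# Default per-frequency true thresholds (dB re 1 uPa) for the evoked
# simulator.  Reproductive males are modelled ~8 dB more sensitive at low
# frequencies; non-reproductive males roll off above 665 Hz (no response).
REP_THRESHOLDS = {95: 121, 190: 124, 285: 127, 380: 130, 475: 133,
                  570: 136, 665: 139, 760: 142, 855: 145, 950: 148}
NR_THRESHOLDS = {95: 129, 190: 132, 285: 135, 380: 138, 475: 141, 570: 144,
                 665: 150}


@dataclass
class RunConfig:
    """Reproducible configuration of one pipeline run."""

    seed: int = 0
    n_per_state: int = 8
    mesh_resolution_morph: float = 1.5       # mm, cohort meshes
    mesh_resolution_fem: float = 2.0         # mm, the two FEM models
    n_landmarks: int = 200
    fem_f_max: float = 750.0
    fem_f_step: float = 25.0
    fem_angles: tuple = tuple(range(0, 360, 45))
    zeta: float = 0.325
    youngs_modulus: float = 1.0e6
    thickness: float = 824.5e-6
    density: float = 1000.0
    poisson_ratio: float = 0.4
    ephys_frequencies: tuple = synthetic.DEFAULT_FREQUENCIES
    ephys_levels: tuple = synthetic.DEFAULT_LEVELS
    subject_threshold_jitter_db: float = 1.5
    iso_levels: tuple = (130, 142, 154)
    make_figures: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("fem_angles", "ephys_frequencies", "ephys_levels", "iso_levels"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d


def run_pipeline(config: RunConfig, out_dir) -> Path:
    """Run every stage; returns the artifact directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("pipeline start: %s", out)

    cohort = _stage_simulate(config, out)
    morph_tbl, scores = _stage_morphometrics(config, cohort, out)
    power_cmp = _stage_fem(config, out)
    curves_by_state, thr_tbl = _stage_ephys(config, cohort, out)
    if config.n_per_state >= 2:
        _stage_stats(config, morph_tbl, thr_tbl, out)
    else:
        log.warning("n_per_state < 2: statistics stage skipped")
    if config.make_figures:
        _figures(out, scores, morph_tbl)

    manifest = {
        "bladderkit_version": __version__,
        "config": config.to_dict(),
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    log.info("pipeline complete")
    return out


def _stage_simulate(config: RunConfig, out: Path):
    log.info("stage simulate: cohort n=%d/state", config.n_per_state)
    cohort = synthetic.generate_cohort(
        config.n_per_state, seed=config.seed,
        mesh_resolution=config.mesh_resolution_morph)
    synthetic.cohort_to_dataframe(cohort).to_csv(out / "cohort.csv", index=False)
    mesh_dir = out / "meshes"
    mesh_dir.mkdir(exist_ok=True)
    for r in cohort:
        synthetic.save_mesh(r.mesh, mesh_dir / f"{r.specimen_id}.stl")
    return cohort


def _stage_morphometrics(config: RunConfig, cohort, out: Path):
    log.info("stage morphometrics")
    tbl = morph.morphometrics_table(cohort)
    tbl.to_csv(out / "morphometrics.csv", index=False)
    if len(cohort) < 3:
        log.warning("fewer than 3 specimens: morphospace stage skipped")
        return tbl, None
    template = cohort[0]
    lm = morph.generate_pseudo_landmarks(template.mesh, config.n_landmarks)
    sets = []
    for r in cohort:
        if r is template:
            sets.append(lm)
        else:
            sets.append(morph.transfer_landmarks(lm, template.mesh, r.mesh))
    space = morph.procrustes_pca(sets)
    scores = space.scores_table(labels=[r.reproductive_state for r in cohort])
    scores.insert(0, "specimen_id", [r.specimen_id for r in cohort])
    scores.to_csv(out / "morphospace_scores.csv", index=False)
    pd.DataFrame({
        "component": np.arange(1, len(space.explained_variance_fraction) + 1),
        "explained_variance_fraction": space.explained_variance_fraction,
    }).to_csv(out / "morphospace_variance.csv", index=False)
    return tbl, scores


def _fem_one_state(config: RunConfig, horned: bool):
    preset = (synthetic.DEFAULT_PRESETS["non-reproductive"] if horned
              else synthetic.DEFAULT_PRESETS["reproductive"])
    shape = synthetic.BladderShapeParams(
        body_length=preset.body_length, body_width=preset.body_width,
        body_height=preset.body_height, horn_length=preset.horn_length,
        mesh_resolution=config.mesh_resolution_fem)
    mesh = synthetic.generate_bladder_mesh(shape)
    model = fem.FemModel.from_mesh_mm(
        mesh, youngs_modulus=config.youngs_modulus, thickness=config.thickness,
        density=config.density, damping_ratio=config.zeta,
        poisson_ratio=config.poisson_ratio)
    K, M = fem.assemble(model)
    system = fem.apply_boundary_conditions(model, K, M)
    modal = fem.modal_analysis(system, f_max=config.fem_f_max)
    sections = fem.section_mesh(mesh)
    points = fem.select_representative_points(mesh, sections, horned=horned)
    grid = fem.response_grid(config.fem_f_max, config.fem_f_step,
                             modal.frequencies_hz)
    responses = {}
    for th in config.fem_angles:
        load = fem.build_pressure_load(model, th)
        responses[th] = fem.harmonic_response(
            modal, load, grid, zeta=config.zeta, points=points)
    return modal, points, responses


def _stage_fem(config: RunConfig, out: Path):
    log.info("stage fem: modal + harmonic for both phenotypes")
    results = {}
    for state, horned in (("non-reproductive", True), ("reproductive", False)):
        modal, points, responses = _fem_one_state(config, horned)
        results[state] = responses
        pd.DataFrame({"mode": np.arange(1, len(modal.frequencies_hz) + 1),
                      "frequency_hz": modal.frequencies_hz}).to_csv(
            out / f"modal_{state}.csv", index=False)
        rows = []
        for th, resp in responses.items():
            P = fem.compute_power(resp)
            for i, f in enumerate(resp.frequencies_hz):
                rows.append({
                    "theta_deg": th, "frequency_hz": f,
                    "mean_displacement_m": resp.magnitude[:, i].mean(),
                    "max_displacement_m": resp.magnitude[:, i].max(),
                    "total_power": P[:, i].sum(),
                })
        pd.DataFrame(rows).to_csv(out / f"frf_{state}.csv", index=False)
    cmp = fem.compare_states(results["non-reproductive"], results["reproductive"],
                             f_max=config.fem_f_max, step=config.fem_f_step)
    cmp = cmp.rename(columns={"power_a": "power_non_reproductive",
                              "power_b": "power_reproductive"})
    cmp.to_csv(out / "power_by_angle.csv", index=False)
    return cmp


def _stage_ephys(config: RunConfig, cohort, out: Path):
    log.info("stage ephys: simulate + threshold %d records", len(cohort))
    rng = np.random.default_rng(config.seed + 1)
    curves_by_state: dict[str, list] = {}
    all_trials = []
    thr_rows = []
    for r in cohort:
        base = (NR_THRESHOLDS if r.reproductive_state == "non-reproductive"
                else REP_THRESHOLDS)
        offset = rng.normal(0.0, config.subject_threshold_jitter_db)
        thr = {f: v + offset for f, v in base.items()}
        params = synthetic.EvokedSimParams(
            true_threshold=thr, seed=int(rng.integers(2**31)))
        ds = synthetic.simulate_evoked_dataset(
            params, config.ephys_frequencies, config.ephys_levels,
            metadata={"subject": r.specimen_id, "state": r.reproductive_state})
        t = ds.trials.copy()
        t.insert(0, "subject", r.specimen_id)
        t.insert(1, "state", r.reproductive_state)
        all_trials.append(t)
        curve = ephys.tuning_curve(ds)
        curves_by_state.setdefault(r.reproductive_state, []).append(curve)
        for f, th_db in zip(curve.frequencies, curve.thresholds):
            thr_rows.append({"subject": r.specimen_id, "state": r.reproductive_state,
                             "frequency_hz": f, "threshold_db": th_db})
    pd.concat(all_trials).to_csv(out / "evoked_trials.csv", index=False)
    thr_tbl = pd.DataFrame(thr_rows)
    thr_tbl.to_csv(out / "thresholds.csv", index=False)

    group_curves = []
    for state, curves in curves_by_state.items():
        g = ephys.group_tuning_curve(curves)
        g.insert(0, "state", state)
        group_curves.append(g)
        d = ephys.detection_rate(curves)
        d.insert(0, "state", state)
        d.to_csv(out / f"detection_rate_{state}.csv", index=False)
    pd.concat(group_curves).to_csv(out / "tuning_curves.csv", index=False)
    if len(curves_by_state) == 2:
        diff = ephys.threshold_difference(
            curves_by_state["non-reproductive"], curves_by_state["reproductive"])
        diff.to_csv(out / "threshold_difference.csv", index=False)
    return curves_by_state, thr_tbl


def _stage_stats(config: RunConfig, morph_tbl: pd.DataFrame,
                 thr_tbl: pd.DataFrame, out: Path):
    log.info("stage stats")
    rows = []
    for measure in ("smsi", "width_norm", "horn_length_norm",
                    "otolith_distance_norm"):
        a = morph_tbl.loc[morph_tbl["state"] == "non-reproductive", measure]
        b = morph_tbl.loc[morph_tbl["state"] == "reproductive", measure]
        res = stats.two_sample_t(a, b)
        rows.append({"measure": measure, "t": res.statistic, "df": res.df[0],
                     "p": res.p_value, "significant": res.significant})
    pd.DataFrame(rows).to_csv(out / "stats_morphometrics.csv", index=False)

    # thresholds: drop frequencies with any no-response cell so the RM design
    # stays balanced, then mixed ANOVA + per-frequency contrasts
    t = thr_tbl.dropna()
    complete = (t.groupby("frequency_hz")["subject"].count()
                == thr_tbl["subject"].nunique())
    keep = complete[complete].index
    bal = t[t["frequency_hz"].isin(keep)]
    if keep.size >= 2 and bal["state"].nunique() == 2:
        res = stats.rm_anova_oneway(bal, dv="threshold_db", subject="subject",
                                    within="frequency_hz", between="state")
        pd.DataFrame([{"test": res.test, "F": res.statistic,
                       "df1": res.df[0], "df2": res.df[1],
                       "p": res.p_value}]).to_csv(
            out / "stats_rm_anova.csv", index=False)
    pw = stats.pairwise_apriori_t(thr_tbl.dropna(), dv="threshold_db",
                                  group="state", frequency="frequency_hz")
    pw.to_csv(out / "stats_pairwise.csv", index=False)


def _figures(out: Path, scores: pd.DataFrame, morph_tbl: pd.DataFrame):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"non-reproductive": "tab:blue", "reproductive": "tab:red"}

    if scores is not None and "PC2" in scores.columns:
        fig, ax = plt.subplots(figsize=(5, 4))
        for state, sub in scores.groupby("label"):
            ax.scatter(sub["PC1"], sub["PC2"], label=state,
                       color=colors.get(state, "k"))
        ax.set_xlabel("PC1")
        ax.set_ylabel("PC2")
        ax.legend()
        fig.tight_layout()
        fig.savefig(out / "fig_morphospace.png", dpi=120)
        plt.close(fig)

    tuning = out / "tuning_curves.csv"
    if tuning.exists():
        df = pd.read_csv(tuning)
        fig, ax = plt.subplots(figsize=(5, 4))
        for state, sub in df.groupby("state"):
            ax.errorbar(sub["frequency_hz"], sub["mean_threshold_db"],
                        yerr=sub["ci_half_width_db"], label=state,
                        color=colors.get(state, "k"), marker="o")
        ax.set_xlabel("frequency (Hz)")
        ax.set_ylabel("threshold (dB re 1 $\\mu$Pa)")
        ax.legend()
        fig.tight_layout()
        fig.savefig(out / "fig_tuning_curves.png", dpi=120)
        plt.close(fig)

    frf = out / "frf_non-reproductive.csv"
    if frf.exists():
        df = pd.read_csv(frf)
        fig, ax = plt.subplots(figsize=(5, 4))
        for th, sub in df.groupby("theta_deg"):
            ax.plot(sub["frequency_hz"], sub["mean_displacement_m"],
                    label=f"{int(th)} deg", alpha=0.7)
        ax.set_yscale("log")
        ax.set_xlabel("frequency (Hz)")
        ax.set_ylabel("mean |U| (m/Pa)")
        ax.legend(fontsize=6, ncol=2)
        fig.tight_layout()
        fig.savefig(out / "fig_frf.png", dpi=120)
        plt.close(fig)

    pw = out / "power_by_angle.csv"
    if pw.exists():
        df = pd.read_csv(pw)
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.bar(df["theta_deg"], df["difference"], width=30)
        ax.set_xlabel("incidence angle (deg)")
        ax.set_ylabel("power difference (NR - Rep)")
        fig.tight_layout()
        fig.savefig(out / "fig_power_difference.png", dpi=120)
        plt.close(fig)
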