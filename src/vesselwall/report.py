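"""Group statistics and figure generation for the analysis pipeline.

Group comparisons use one-way ANOVA with Bonferroni-corrected pairwise
t-tests (significance at p < 0.05).  Summary statistics follow the field's
reporting convention: mean ± SEM for mechanical metrics, mean ± SD for
imaging-derived metrics.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import ValidationError

__all__ = [
    "GroupComparison",
    "group_compare",
    "group_summary",
    "make_figures",
    "MECHANICS_METRICS",
    "IMAGING_METRICS",
]

#: Metrics reported as mean ± SEM (mechanical testing convention).
MECHANICS_METRICS = frozenset(
    {"lambda_iv", "sigma_theta_map", "sigma_z_map", "tangent_modulus", "lambda_theta_map"}
)
#: Metrics reported as mean ± SD (multiphoton imaging convention).
IMAGING_METRICS = frozenset(
    {"ps_mean_of_medians", "qc_qa_media", "qc_qa_adventitia", "interface_depth"}
)

SIGNIFICANCE_LEVEL = 0.05


@dataclass
class GroupComparison:
    """One-way ANOVA across groups plus Bonferroni-adjusted pairwise tests."""

    metric: str
    groups: list[str]
    f_statistic: float
    p_value: float
    pairwise: pd.DataFrame  # columns: group_a, group_b, p_raw, p_bonferroni, significant
    alpha: float = SIGNIFICANCE_LEVEL

    @property
    def significant(self) -> bool:
        return bool(self.p_value < self.alpha)


def group_compare(
    table: pd.DataFrame,
    metric: str,
    group_col: str = "group",
    alpha: float = SIGNIFICANCE_LEVEL,
) -> GroupComparison:
    """Compare a metric across groups: one-way ANOVA + Bonferroni post hoc.

    ``table`` has one row per sample with a ``group`` label column.  The
    Bonferroni-adjusted pairwise p-value is min(1, raw p × number of pairs).
    """
    if metric not in table.columns:
        raise ValidationError(f"metric {metric!r} not in table columns {list(table.columns)}")
    samples = {
        g: sub[metric].dropna().to_numpy(dtype=float)
        for g, sub in table.groupby(group_col, sort=True)
    }
    if len(samples) < 2:
        raise ValidationError("need ≥ 2 groups")
    for g, x in samples.items():
        if len(x) < 2:
            raise ValidationError(f"group {g!r} has < 2 samples for {metric!r}")
    names = list(samples)
    f_stat, p_val = stats.f_oneway(*samples.values())

    pairs = list(itertools.combinations(names, 2))
    rows = []
    for a, b in pairs:
        _, p_raw = stats.ttest_ind(samples[a], samples[b])
        p_adj = min(1.0, float(p_raw) * len(pairs))
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "p_raw": float(p_raw),
                "p_bonferroni": p_adj,
                "significant": p_adj < alpha,
            }
        )
    return GroupComparison(
        metric=metric,
        groups=names,
        f_statistic=float(f_stat),
        p_value=float(p_val),
        pairwise=pd.DataFrame(rows),
        alpha=alpha,
    )


def group_summary(table: pd.DataFrame, group_col: str = "group") -> pd.DataFrame:
    """Mean ± spread per group and metric.

    The spread is SEM for mechanics metrics and SD for imaging metrics
    (matching the reporting convention declared in the module docstring);
    unknown metrics default to SEM with a warning.
    """
    rows = []
    metrics = [c for c in table.columns if c != group_col and np.issubdtype(table[c].dtype, np.number)]
    for metric in metrics:
        if metric in IMAGING_METRICS:
            spread_kind = "sd"
        else:
            if metric not in MECHANICS_METRICS:
                warnings.warn(f"metric {metric!r} not classified; reporting SEM", stacklevel=2)
            spread_kind = "sem"
        for g, sub in table.groupby(group_col, sort=True):
            x = sub[metric].dropna().to_numpy(dtype=float)
            if len(x) == 0:
                continue
            sd = float(np.std(x, ddof=1)) if len(x) > 1 else math.nan
            spread = sd / math.sqrt(len(x)) if spread_kind == "sem" else sd
            rows.append(
                {
                    "metric": metric,
                    "group": g,
                    "n": len(x),
                    "mean": float(np.mean(x)),
                    "spread": spread,
                    "spread_kind": spread_kind,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Figures
# ---------------------------------------------------------------------------


def make_figures(results: dict, output_dir: str | Path) -> list[Path]:
    """Emit the standard figure set from a completed pipeline-results dict.

    Recognised keys (each optional; missing metrics produce a warning and the
    figure is skipped):

    - ``mechanics``: list of per-sweep dicts with ``pressures``, ``d_o``,
      ``f``, ``sigma_theta``, ``sigma_z``, ``lambda_theta``, ``label``
    - ``straightness``: dict with ``depth_table`` (depth_um, ps_bin, count)
    - ``orientation_hist``: dict angle -> density (stack average)
    - ``depth_map``: dict with ``depths``, ``angles``, ``density`` (2-D),
      optional ``interface_depth``
    - ``group_table``: per-sample metric table with a ``group`` column

    Returns the list of written figure paths.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _save(fig, name: str) -> None:
        path = outdir / name
        fig.savefig(path, dpi=150)
        plt.close(fig)
        written.append(path)

    mech = results.get("mechanics")
    if mech:
        for key, ylabel, name in (
            ("d_o", "Outer diameter (µm)", "pressure_diameter.png"),
            ("f", "Axial force (mN)", "force_pressure.png"),
        ):
            fig, ax = plt.subplots(figsize=(5, 4))
            for sw in mech:
                ax.plot(sw["pressures"], sw[key], marker="o", label=sw.get("label", ""))
            ax.set_xlabel("Pressure (mmHg)")
            ax.set_ylabel(ylabel)
            ax.legend(fontsize=8)
            fig.tight_layout()
            _save(fig, name)
        fig, ax = plt.subplots(figsize=(5, 4))
        for sw in mech:
            ax.plot(sw["lambda_theta"], sw["sigma_theta"], marker="o",
                    label=f"{sw.get('label','')} σθ")
            ax.plot([sw["axial_stretch"]] * len(sw["sigma_z"]), sw["sigma_z"],
                    marker="s", ls="--", label=f"{sw.get('label','')} σz")
        ax.set_xlabel("Stretch ratio")
        ax.set_ylabel("Cauchy stress (kPa)")
        ax.legend(fontsize=7)
        fig.tight_layout()
        _save(fig, "stress_stretch.png")
    else:
        warnings.warn("no mechanics results; skipping mechanics figures", stacklevel=2)

    ps = results.get("straightness")
    if ps is not None and len(ps.get("depth_table", [])):
        df = pd.DataFrame(ps["depth_table"])
        fig = plt.figure(figsize=(6, 5))
        ax = fig.add_subplot(projection="3d")
        for depth, sub in df.groupby("depth_um"):
            ax.bar(sub["ps_bin"], sub["count"], zs=depth, zdir="y",
                   width=float(np.diff(sorted(sub["ps_bin"].unique()))[0]) if sub["ps_bin"].nunique() > 1 else 0.02,
                   alpha=0.7)
        ax.set_xlabel("$P_s$")
        ax.set_ylabel("Depth (µm)")
        ax.set_zlabel("Fiber count")
        _save(fig, "straightness_3d.png")
    else:
        warnings.warn("no straightness results; skipping 3-D bar plot", stacklevel=2)

    oh = results.get("orientation_hist")
    if oh:
        angles = np.array(sorted(oh, key=float), dtype=float)
        dens = np.array([oh[a] for a in sorted(oh, key=float)], dtype=float)
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.bar(angles, dens, width=180.0 / len(angles))
        ax.set_xlabel("Orientation (°); 0 = axial, ±90 = circumferential")
        ax.set_ylabel("Density")
        fig.tight_layout()
        _save(fig, "orientation_hist.png")
    else:
        warnings.warn("no orientation histogram; skipping", stacklevel=2)

    dm = results.get("depth_map")
    if dm:
        fig, ax = plt.subplots(figsize=(6, 4))
        mesh = ax.pcolormesh(
            np.asarray(dm["angles"], float),
            np.asarray(dm["depths"], float),
            np.asarray(dm["density"], float),
            shading="auto",
        )
        fig.colorbar(mesh, ax=ax, label="Density")
        if dm.get("interface_depth") is not None:
            ax.axhline(dm["interface_depth"], color="red", lw=2)
        ax.set_xlabel("Orientation (°)")
        ax.set_ylabel("Depth (µm)")
        ax.invert_yaxis()
        fig.tight_layout()
        _save(fig, "depth_orientation_map.png")
    else:
        warnings.warn("no depth map; skipping surface plot", stacklevel=2)

    gt = results.get("group_table")
    if gt is not None and len(gt):
        gt = pd.DataFrame(gt)
        summ = group_summary(gt)
        for metric in ("qc_qa_media", "tangent_modulus"):
            sub = summ[summ["metric"] == metric]
            if not len(sub):
                continue
            fig, ax = plt.subplots(figsize=(4, 4))
            ax.bar(sub["group"], sub["mean"], yerr=sub["spread"], capsize=4)
            kind = sub["spread_kind"].iloc[0].upper()
            ax.set_ylabel(f"{metric} (mean ± {kind})")
            fig.tight_layout()
            _save(fig, f"group_{metric}.png")
    else:
        warnings.warn("no group table; skipping group bar charts", stacklevel=2)

    return written


# ---------------------------------------------------------------------------
# End-to-end pipeline over a sample manifest
# ---------------------------------------------------------------------------


def run_manifest(config: dict, output_dir: str | Path, figures: bool = False) -> dict:
    """Run the full analysis over a manifest of synthetic samples.

    ``config`` declares groups, their mean arterial pressure (MAP) and
    per-sample generator parameters::

        reference_pressure: 100        # fallback MAP, mmHg
        groups:
          CTL:
            map: 100
            samples:
              - id: ctl1
                seed: 11
                model: {c: 25, c1: 15, c2: 1.5, alpha_deg: 60,
                        diameter_noise_sd: 0.01, force_noise_sd: 0.02}
        imaging:                        # optional; enables microstructure metrics
          n_frames: 8
          interface_frame: 4
          image_size: [128, 128]
          n_fibers: 8
          amplitude: 4.0

    For every sample the vessel's force-invariant stretch λ* is located,
    three sweeps at λ*·(0.95, 1, 1.05) are simulated, the in vivo stretch is
    re-estimated from the (noisy) sweeps and the sweep nearest λ_iv is
    processed for stresses and tangent modulus at the group MAP.  When an
    ``imaging`` section is present, a collagen-like stack drives the
    straightness summary and an elastin-like stack with an orientation flip
    drives Q_C/Q_A and interface detection.  Everything is seeded from the
    per-sample seed, so repeated runs are bit-identical.

    Writes ``metrics.csv`` (one row per sample), ``summary.json`` and, with
    ``figures=True``, the standard figure set.  Returns the summary dict.
    """
    import json

    from .data_io import RingGeometry
    from .fiber_trace import stack_straightness
    from .mechanics import estimate_in_vivo_stretch, process_sweep
    from .orientation import (
        average_distribution,
        depth_orientation_map,
        detect_interface,
        qc_qa_ratio,
    )
    from .synth import (
        FiberFieldSpec,
        VesselModel,
        apply_observation_noise,
        axial_to_circumferential_specs,
        find_force_invariant_stretch,
        render_fiber_stack,
        simulate_sweep,
    )

    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    default_map = float(config.get("reference_pressure", 100.0))
    imaging_cfg = config.get("imaging")

    lam_star_cache: dict[tuple, float] = {}
    rows = []
    mech_figs = []
    for group_name, group_cfg in config["groups"].items():
        group_map = float(group_cfg.get("map", default_map))
        for sample in group_cfg["samples"]:
            sid = sample.get("id", f"{group_name}-{sample['seed']}")
            seed = int(sample["seed"])
            model = VesselModel(**sample.get("model", {}))
            mech_key = (
                model.D_i, model.D_o, model.c, model.c1, model.c2, model.alpha_deg,
            )
            if mech_key not in lam_star_cache:
                lam_star_cache[mech_key] = find_force_invariant_stretch(model)
            lam_star = lam_star_cache[mech_key]

            sweeps = []
            for j, fac in enumerate((0.95, 1.0, 1.05)):
                _, truth = simulate_sweep(model, lam_star * fac, seed=None)
                sweeps.append(
                    apply_observation_noise(truth, model, seed=seed * 10 + j, label=sid)
                )
            iv = estimate_in_vivo_stretch(sweeps)
            k_iv = int(np.argmin([abs(s.axial_stretch - iv.lambda_iv) for s in sweeps]))
            ring = RingGeometry(math.pi * model.D_i, math.pi * model.D_o)
            res = process_sweep(sweeps[k_iv], ring, reference_pressure=group_map)
            k_map = int(np.argmin(np.abs(sweeps[k_iv].pressures - group_map)))
            row = {
                "sample": sid,
                "group": group_name,
                "lambda_iv": iv.lambda_iv,
                "sigma_theta_map": res.sigma_theta[k_map],
                "sigma_z_map": res.sigma_z[k_map],
                "lambda_theta_map": res.lambda_theta_at_reference,
                "tangent_modulus": res.tangent_modulus_theta,
            }
            mech_figs.append(
                {
                    "pressures": sweeps[k_iv].pressures.tolist(),
                    "d_o": sweeps[k_iv].outer_diameters.tolist(),
                    "f": sweeps[k_iv].axial_forces.tolist(),
                    "sigma_theta": res.sigma_theta.tolist(),
                    "sigma_z": res.sigma_z.tolist(),
                    "lambda_theta": res.lambda_theta.tolist(),
                    "axial_stretch": sweeps[k_iv].axial_stretch,
                    "label": sid,
                }
            )

            if imaging_cfg:
                base = FiberFieldSpec(
                    n_fibers=int(imaging_cfg.get("n_fibers", 8)),
                    amplitude=float(imaging_cfg.get("amplitude", 4.0)),
                    image_size=tuple(imaging_cfg.get("image_size", (128, 128))),
                    fiber_length=float(imaging_cfg.get("fiber_length", 90.0)),
                )
                n_frames = int(imaging_cfg.get("n_frames", 8))
                interface_frame = int(imaging_cfg.get("interface_frame", n_frames // 2))
                specs = axial_to_circumferential_specs(
                    n_frames, interface_frame, base=base, seed=seed
                )
                stack, _ = render_fiber_stack(specs, interface_depth=float(interface_frame))
                ps = stack_straightness(stack)
                dmap = depth_orientation_map(stack)
                interface = detect_interface(dmap)
                row["ps_mean_of_medians"] = ps.mean_of_medians
                row["interface_depth"] = interface if interface is not None else np.nan
                if interface is not None:
                    k_if = int(np.argmin(np.abs(dmap.depths - interface)))
                    adv = dmap.distributions[:k_if]
                    med = dmap.distributions[k_if + 1 :]
                    if adv:
                        row["qc_qa_adventitia"] = qc_qa_ratio(average_distribution(adv)).ratio
                    if med:
                        row["qc_qa_media"] = qc_qa_ratio(average_distribution(med)).ratio
            rows.append(row)

    table = pd.DataFrame(rows)
    table.to_csv(outdir / "metrics.csv", index=False, float_format="%.10g")

    summary: dict = {"n_samples": len(table), "groups": sorted(config["groups"])}
    summ = group_summary(table)
    summary["group_summary"] = summ.to_dict(orient="records")
    comparisons = []
    counts = table.groupby("group")["sample"].count()
    if len(counts) >= 2 and (counts >= 2).all():
        for metric in table.columns:
            if metric in ("sample", "group") or table[metric].isna().all():
                continue
            if np.nanstd(table[metric].to_numpy(dtype=float)) == 0:
                continue  # constant metric: ANOVA undefined
            try:
                cmp_res = group_compare(table, metric)
            except ValidationError:
                continue
            comparisons.append(
                {
                    "metric": metric,
                    "F": cmp_res.f_statistic,
                    "p": cmp_res.p_value,
                    "pairwise": cmp_res.pairwise.to_dict(orient="records"),
                }
            )
    summary["comparisons"] = comparisons
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))

    if figures:
        make_figures(
            {"mechanics": mech_figs, "group_table": table.to_dict(orient="records")},
            outdir / "figures",
        )
    return summary
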