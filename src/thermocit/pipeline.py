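"""End-to-end pipeline: simulate/load -> FTCV stats -> smooth -> FANOVA -> FLD.

Stage order mirrors the study: scalar FTCV inference on the raw windows;
then baseline correction, decimation, roughness-penalty smoothing and the
functional ANOVA; finally the penalized functional discriminant run
separately on the relevant-question and irrelevant-question functions,
with rho selected by leave-one-out cross-validation.  Every stochastic
stage draws from the single seed in the configuration, so a rerun with
the same config is byte-identical.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np

from . import discriminant as fld
from . import fanova as fan
from . import preprocess as pre
from . import scalar_stats as sst
from . import smoothing as smo
from .generate import generate_dataset
from .io import (
    RunConfig,
    dump_json,
    read_baselines_csv,
    read_long_csv,
    write_baselines_csv,
    write_basis_json,
    write_coefficients_csv,
    write_long_csv,
)

log = logging.getLogger("thermocit.pipeline")


def _scalar_report(table: dict) -> dict:
    """The study's scalar analyses on the per-participant FTCV table."""
    out = {}
    g_re, g_ir = table[("guilty", "RE")], table[("guilty", "IR")]
    i_re, i_ir = table[("innocent", "RE")], table[("innocent", "IR")]
    for name, arr in (("GC-RE", g_re), ("GC-IR", g_ir), ("IC-RE", i_re), ("IC-IR", i_ir)):
        out[f"shapiro_{name}"] = sst.shapiro_wilk(arr).to_dict()
    gc = sst.paired_t_directional(g_re, g_ir, tail="greater")
    ic = sst.paired_t_directional(i_re, i_ir, tail="greater")
    # two directional paired tests -> Bonferroni m = 2
    out["paired_t_GC"] = {**gc.to_dict(), "adjusted_p": sst.bonferroni_adjust(gc.p_value, 2)}
    out["paired_t_IC"] = {**ic.to_dict(), "adjusted_p": sst.bonferroni_adjust(ic.p_value, 2)}
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages, write artifacts under config.outdir, return the report."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": config.to_dict()}

    def stage(name):
        log.info("stage %s starting", name)
        return time.perf_counter()

    def done(name, t0):
        dt = time.perf_counter() - t0
        report.setdefault("timings_s", {})[name] = round(dt, 3)
        log.info("stage %s finished in %.2f s", name, dt)

    # ---- simulate or load -------------------------------------------------
    t0 = stage("simulate")
    try:
        if config.input_csv:
            samples = read_long_csv(config.input_csv)
            baselines = read_baselines_csv(config.baselines_csv) if config.baselines_csv else None
            dataset = None
        else:
            dataset = generate_dataset(config.simulate)
            samples = dataset.samples
            baselines = dataset.baselines
            write_long_csv(dataset, outdir / "dataset.csv")
            write_baselines_csv(baselines, outdir / "baselines.csv")
    except Exception as exc:
        raise type(exc)(f"[simulate] {exc}") from exc
    done("simulate", t0)

    # ---- scalar FTCV statistics ------------------------------------------
    if baselines is not None and dataset is not None:
        t0 = stage("ftcv")
        try:
            table = pre.ftcv_table(dataset, baselines)
            report["scalar_stats"] = _scalar_report(table)
            report["ftcv_means"] = {f"{c}-{r}": float(np.mean(v)) for (c, r), v in table.items()}
            dump_json(report["scalar_stats"], outdir / "scalar_stats.json")
        except Exception as exc:
            raise type(exc)(f"[ftcv] {exc}") from exc
        done("ftcv", t0)

    # ---- preprocess: baseline-correct + decimate --------------------------
    t0 = stage("preprocess")
    try:
        if baselines:
            corrected = [pre.baseline_correct(s, baselines[s.participant_id]) for s in samples]
        else:
            corrected = list(samples)
        decimated = [pre.decimate(s, config.preprocess.decimate_every) for s in corrected]
    except Exception as exc:
        raise type(exc)(f"[preprocess] {exc}") from exc
    done("preprocess", t0)

    # ---- smoothing ---------------------------------------------------------
    t0 = stage("smooth")
    try:
        times = decimated[0].times
        window = float(times[-1])
        n_basis = config.smooth.n_basis or (len(times) + config.smooth.order - 2)
        basis = smo.build_basis(window, n_basis, config.smooth.order)
        smoothed = smo.smooth_many(decimated, basis, smo.SmoothConfig(lam=config.smooth.lam))
        write_basis_json(basis, outdir / "basis.json")
        write_coefficients_csv(smoothed, outdir / "coefficients.csv")
    except Exception as exc:
        raise type(exc)(f"[smooth] {exc}") from exc
    done("smooth", t0)

    # ---- functional ANOVA --------------------------------------------------
    t0 = stage("fanova")
    try:
        result = fan.fit_fanova(smoothed, times)
        fan.pointwise_ci(result, smoothed, level=config.fanova.ci_level)
        fan.effects_table(result).to_csv(outdir / "fanova_effects.tsv", sep="\t", index=False)
        report["fanova"] = {
            name: {
                "mean_abs": float(np.mean(np.abs(result.effect(name)))),
                "max_abs": float(np.max(np.abs(result.effect(name)))),
                "significant_fraction": float(np.mean(fan.effect_significant(result, name))),
            }
            for name in fan.EFFECTS
        }
    except Exception as exc:
        raise type(exc)(f"[fanova] {exc}") from exc
    done("fanova", t0)

    # ---- functional discriminant, RE and IR separately --------------------
    # unlike the FANOVA, the discriminant uses the full-resolution windows:
    # decimation was only ever a FANOVA cost-saving measure
    t0 = stage("discriminate")
    try:
        full_times = corrected[0].times
        full_basis = smo.build_basis(
            float(full_times[-1]), len(full_times) + config.smooth.order - 2, config.smooth.order
        )
        full_smoothed = smo.smooth_many(corrected, full_basis, smo.SmoothConfig(lam=config.smooth.lam))
        report["discriminant"] = {}
        for relevance in ("RE", "IR"):
            fns = [f for f in full_smoothed if f.relevance == relevance]
            if config.discriminate.use_loocv:
                rho, cv = fld.loocv_select_rho(fns, rho_grid=config.discriminate.rho_grid)
            else:
                rho, cv = config.discriminate.rho, {}
            model = fld.fit_fld(fns, config=fld.DiscriminantConfig(rho=rho, rho_grid=config.discriminate.rho_grid))
            rep = fld.classify(model, fns)
            entry = {
                **rep.to_dict(),
                "rho": rho,
                "cv_curve": {f"{r:g}": e for r, e in cv.items()},
                "loocv_error": cv.get(rho),
            }
            report["discriminant"][relevance] = entry
            dump_json(entry, outdir / f"discriminant_{relevance.lower()}.json")
    except Exception as exc:
        raise type(exc)(f"[discriminate] {exc}") from exc
    done("discriminate", t0)

    dump_json(report, outdir / "report.json")
    return report


def fanova_panel_figure(effects_tsv, out_png) -> None:
    """4-panel effect-function figure (grand mean + three effects with bands)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import pandas as pd

    df = pd.read_csv(effects_tsv, sep="\t")
    fig, axes = plt.subplots(2, 2, figsize=(10, 7), sharex=True)
    titles = {
        "mu": "Grand mean function",
        "alpha": "Condition effect (guilty side)",
        "beta": "Relevance effect (RE side)",
        "gamma": "Condition x relevance interaction",
    }
    for ax, term in zip(axes.ravel(), ("mu", "alpha", "beta", "gamma")):
        sub = df[df["term"] == term]
        ax.plot(sub["time_s"], sub["estimate"], "k-")
        if sub["ci_lower"].notna().any():
            ax.plot(sub["time_s"], sub["ci_lower"], "k:", lw=0.8)
            ax.plot(sub["time_s"], sub["ci_upper"], "k:", lw=0.8)
        if term != "mu":
            ax.axhline(0.0, color="0.7", lw=0.6)
        ax.set_title(titles[term])
        ax.set_ylabel("temperature (degC)")
    for ax in axes[-1]:
        ax.set_xlabel("time (s)")
    fig.tight_layout()
    fig.savefig(out_png, dpi=150)
    plt.close(fig)
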