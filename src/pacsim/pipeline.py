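"""End-to-end study driver.

Reproduces the full treatment-selection workflow on synthetic (or
user-supplied) two-arm cohorts: bidirectional group-similarity check,
per-arm PCR outcome models with outlier screening, counterfactual
cross-arm prediction with ±3·RMSEP intervals, derivation of the full
decision indicator, backward elimination to the short indicator, and
per-patient recommendations.  All randomness flows from the seeds in
the study configuration, so repeated runs write byte-identical tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort_io import Cohort, load_cohort, write_cohort
from .ddsimca import SimilarityResult, fit_simca, similarity_test
from .indicator import (
    IndicatorModel,
    backward_select,
    derive_full_indicator,
    evaluate,
    recommend,
)
from .pcr import PCRModel, fit_with_outlier_removal, predict_with_interval
from .synthetic_cohort import (
    GeneratorConfig,
    default_config,
    generate_cohort,
    simulate_outcomes,
)

log = logging.getLogger("pacsim")


@dataclass
class StudyConfig:
    """Parameters of one study run (defaults mirror the original design)."""

    n_per_arm: int = 30
    seed: int = 1
    alpha: float = 0.01  # similarity significance
    gamma: float = 0.01  # outlier significance
    a: int = 2  # PCR components
    K: int | None = None  # CV segments; None = leave-one-out
    p_level: float = 0.05  # elimination F-test level
    gray_halfwidth: float = 1.0  # mm Hg
    generator: GeneratorConfig | None = None
    cohort_le: str | Path | None = None  # optional user cohorts (CSV)
    cohort_lpi: str | Path | None = None

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1 and 0 < self.gamma < 1 and 0 < self.p_level < 1):
            raise ValueError("significance levels must lie in (0, 1)")
        if self.gray_halfwidth < 0:
            raise ValueError("gray half-width must be >= 0")


@dataclass
class StudyReport:
    config: StudyConfig
    cohort_le: Cohort
    cohort_lpi: Cohort
    similarity_le_vs_lpi: SimilarityResult
    similarity_lpi_vs_le: SimilarityResult
    model_le: PCRModel
    model_lpi: PCRModel
    counterfactual: pd.DataFrame
    full_indicator: IndicatorModel
    short_indicator: IndicatorModel
    recommendations: pd.DataFrame
    indicator_values: pd.DataFrame  # per-patient full and short values
    warnings: list[str] = field(default_factory=list)

    @property
    def replacement_rms(self) -> float:
        diff = (
            self.indicator_values["ind_full"] - self.indicator_values["ind_short"]
        ).to_numpy()
        return float(np.sqrt(np.mean(diff**2)))

    @property
    def indicator_correlation(self) -> float:
        full = self.indicator_values["ind_full"].to_numpy()
        short = self.indicator_values["ind_short"].to_numpy()
        if np.std(full) == 0 or np.std(short) == 0:
            return float("nan")  # intercept-only indicator: undefined
        return float(np.corrcoef(full, short)[0, 1])


def counterfactual_table(
    m_le: PCRModel, m_lpi: PCRModel, arm_le: Cohort, arm_lpi: Cohort
) -> pd.DataFrame:
    """Actual ΔIOP next to the other arm's predicted ΔIOP per patient.

    LPI patients get the LE model's prediction (what lens extraction
    would have achieved) and vice versa; each prediction carries the
    predicting model's ±3·RMSEP half-width.  Rows lacking a
    post-treatment pressure are skipped with a warning.
    """
    pieces = []
    for cohort, model, other in (
        (arm_lpi, m_le, "LE"),
        (arm_le, m_lpi, "LPI"),
    ):
        observed = cohort.delta_iop
        usable = observed.notna()
        if (~usable).any():
            log.warning(
                "skipping %d row(s) without IOP_post in %s arm",
                int((~usable).sum()),
                cohort.arm.iloc[0] if cohort.n else "?",
            )
        sub = cohort.subset(usable.to_numpy())
        pred, half = predict_with_interval(model, sub.X)
        pieces.append(
            pd.DataFrame(
                {
                    "patient_id": sub.data["patient_id"],
                    "arm": sub.arm,
                    "PAS_present": sub.pas,
                    "actual_delta_iop": sub.delta_iop.to_numpy(),
                    "counterfactual_arm": other,
                    "predicted_delta_iop": pred,
                    "interval_halfwidth": half,
                }
            )
        )
    return pd.concat(pieces, ignore_index=True)


def _prepare_arm(
    cfg: StudyConfig, arm: str, seed_gen: int, seed_out: int
) -> tuple[Cohort, object]:
    path = cfg.cohort_le if arm == "LE" else cfg.cohort_lpi
    if path is not None:
        cohort = load_cohort(path)
        return cohort, None
    gen = cfg.generator or default_config()
    cohort = generate_cohort(gen, cfg.n_per_arm, seed_gen)
    cohort, truth = simulate_outcomes(cohort, gen, arm, seed_out)
    # disambiguate patient ids across arms
    cohort.data["patient_id"] = [f"{arm}-{pid}" for pid in cohort.data["patient_id"]]
    return cohort, truth


def run_study(cfg: StudyConfig) -> StudyReport:
    """Execute the whole workflow; deterministic given cfg seeds."""
    ss = np.random.SeedSequence(cfg.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(6)]
    warnings_log: list[str] = []

    log.info("generating/loading cohorts")
    arm_le, truth_le = _prepare_arm(cfg, "LE", seeds[0], seeds[1])
    arm_lpi, truth_lpi = _prepare_arm(cfg, "LPI", seeds[2], seeds[3])

    log.info("similarity testing (both directions)")
    simca_le = fit_simca(arm_le.X, a=cfg.a, alpha=cfg.alpha)
    simca_lpi = fit_simca(arm_lpi.X, a=cfg.a, alpha=cfg.alpha)
    sim_le_lpi = similarity_test(simca_le, arm_lpi.X)
    sim_lpi_le = similarity_test(simca_lpi, arm_le.X)
    for label, res in (
        ("LPI-vs-LE-model", sim_le_lpi),
        ("LE-vs-LPI-model", sim_lpi_le),
    ):
        if not res.similar:
            msg = f"similarity test failed ({label}): empirical power {res.empirical:.2f}"
            warnings_log.append(msg)
            log.warning(msg)

    log.info("fitting per-arm PCR models (outlier loop)")
    names = arm_le.schema.names
    model_le = fit_with_outlier_removal(
        arm_le.X,
        arm_le.delta_iop.to_numpy(),
        a=cfg.a,
        K=cfg.K,
        gamma=cfg.gamma,
        seed=seeds[4],
    )
    model_le.feature_names = names
    model_lpi = fit_with_outlier_removal(
        arm_lpi.X,
        arm_lpi.delta_iop.to_numpy(),
        a=cfg.a,
        K=cfg.K,
        gamma=cfg.gamma,
        seed=seeds[5],
    )
    model_lpi.feature_names = names

    log.info("counterfactual cross-arm prediction")
    cf = counterfactual_table(model_le, model_lpi, arm_le, arm_lpi)

    log.info("deriving indicators")
    pooled = pd.concat([arm_le.data, arm_lpi.data], ignore_index=True)
    pooled_X = pooled[names]
    full = derive_full_indicator(model_le, model_lpi, cfg.gray_halfwidth)
    ind_full = evaluate(full, pooled_X)
    # the indicator is only known to the accuracy of the two arm models
    ind_se = float(np.sqrt(model_le.rmsecv**2 + model_lpi.rmsecv**2))
    short = backward_select(
        ind_full,
        pooled_X,
        p_level=cfg.p_level,
        gray_halfwidth=cfg.gray_halfwidth,
        noise_scale=ind_se,
    )
    short.provenance["fitted_on"] = "synthetic-data derived (will not match published coefficients)"
    ind_short = evaluate(short, pooled_X) * np.ones(len(pooled_X))

    values = pd.DataFrame(
        {
            "patient_id": pooled["patient_id"],
            "arm": pooled["arm"],
            "ind_full": ind_full,
            "ind_short": ind_short,
        }
    )
    recs = [recommend(v, cfg.gray_halfwidth) for v in ind_short]
    recommendations = pd.DataFrame(
        {
            "patient_id": pooled["patient_id"],
            "indicator": [r.value for r in recs],
            "decision": [r.decision for r in recs],
        }
    )

    return StudyReport(
        config=cfg,
        cohort_le=arm_le,
        cohort_lpi=arm_lpi,
        similarity_le_vs_lpi=sim_le_lpi,
        similarity_lpi_vs_le=sim_lpi_le,
        model_le=model_le,
        model_lpi=model_lpi,
        counterfactual=cf,
        full_indicator=full,
        short_indicator=short,
        recommendations=recommendations,
        indicator_values=values,
        warnings=warnings_log,
    )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _indicator_json(ind: IndicatorModel) -> dict:
    return {
        "variant": ind.variant,
        "intercept": ind.intercept,
        "slopes": ind.slopes,
        "gray_halfwidth": ind.gray_halfwidth,
        "provenance": {k: str(v) for k, v in ind.provenance.items()},
    }


def report_render(report: StudyReport, outdir: str | Path) -> dict:
    """Write CSV tables, diagnostic figures and a JSON manifest.

    Returns the manifest dictionary.  CSV numeric content is formatted
    canonically so re-runs with identical seeds are byte-identical.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    files: dict[str, str] = {}

    def save_csv(frame: pd.DataFrame, name: str) -> None:
        path = outdir / name
        frame.to_csv(path, index=False, float_format="%.6g")
        files[name.removesuffix(".csv")] = name

    log.info("writing tables to %s", outdir)
    write_cohort(report.cohort_le, outdir / "cohort_LE.csv")
    files["cohort_LE"] = "cohort_LE.csv"
    write_cohort(report.cohort_lpi, outdir / "cohort_LPI.csv")
    files["cohort_LPI"] = "cohort_LPI.csv"
    save_csv(report.counterfactual, "counterfactual.csv")
    save_csv(report.recommendations, "recommendations.csv")
    save_csv(report.indicator_values, "indicator_values.csv")

    log.info("rendering figures")
    for arm, other in (("LPI", "LE"), ("LE", "LPI")):
        sub = report.counterfactual[report.counterfactual["arm"] == arm]
        fig, ax = plt.subplots(figsize=(7, 4))
        idx = np.arange(len(sub))
        ax.scatter(idx, sub["actual_delta_iop"], color="tab:blue", label=f"actual ΔIOP ({arm})")
        ax.errorbar(
            idx,
            sub["predicted_delta_iop"],
            yerr=sub["interval_halfwidth"],
            fmt="o",
            color="tab:red",
            alpha=0.8,
            label=f"predicted ΔIOP under {other} (±3·RMSEP)",
        )
        pas_idx = idx[sub["PAS_present"].to_numpy() == 1]
        for i in pas_idx:
            ax.annotate("PAS", (i, float(sub["actual_delta_iop"].iloc[i])), fontsize=7)
        ax.set_xlabel("patient")
        ax.set_ylabel("ΔIOP, mm Hg")
        ax.legend()
        fig.tight_layout()
        name = f"counterfactual_{arm}.png"
        fig.savefig(outdir / name, dpi=120)
        plt.close(fig)
        files[f"fig_counterfactual_{arm}"] = name

    fig, ax = plt.subplots(figsize=(5, 5))
    v = report.indicator_values
    ax.scatter(v["ind_full"], v["ind_short"], s=18)
    lims = [
        min(v["ind_full"].min(), v["ind_short"].min()),
        max(v["ind_full"].max(), v["ind_short"].max()),
    ]
    ax.plot(lims, lims, "k--", lw=1, label="identity")
    ax.set_xlabel("full indicator, mm Hg")
    ax.set_ylabel("short indicator, mm Hg")
    ax.legend()
    fig.tight_layout()
    fig.savefig(outdir / "indicator_correlation.png", dpi=120)
    plt.close(fig)
    files["fig_indicator_correlation"] = "indicator_correlation.png"

    manifest = {
        "schema_version": 1,
        "package_version": __version__,
        "seed": report.config.seed,
        "n_per_arm": report.config.n_per_arm,
        "n_patients": int(len(report.recommendations)),
        "similarity": {
            "LE_model_vs_LPI": {
                "empirical": report.similarity_le_vs_lpi.empirical,
                "theoretical": report.similarity_le_vs_lpi.theoretical,
                "similar": bool(report.similarity_le_vs_lpi.similar),
            },
            "LPI_model_vs_LE": {
                "empirical": report.similarity_lpi_vs_le.empirical,
                "theoretical": report.similarity_lpi_vs_le.theoretical,
                "similar": bool(report.similarity_lpi_vs_le.similar),
            },
        },
        "models": {
            "LE": {
                "rmsec": report.model_le.rmsec,
                "rmsecv": report.model_le.rmsecv,
                "components": report.model_le.a,
                "removed_outliers": report.model_le.removed,
            },
            "LPI": {
                "rmsec": report.model_lpi.rmsec,
                "rmsecv": report.model_lpi.rmsecv,
                "components": report.model_lpi.a,
                "removed_outliers": report.model_lpi.removed,
            },
        },
        "indicators": {
            "full": _indicator_json(report.full_indicator),
            "short": _indicator_json(report.short_indicator),
            "replacement_rms": report.replacement_rms,
            "correlation": report.indicator_correlation,
        },
        "decision_counts": report.recommendations["decision"].value_counts().to_dict(),
        "warnings": report.warnings,
        "files": files,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    files["manifest"] = "manifest.json"
    return manifest
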