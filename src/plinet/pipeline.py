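"""End-to-end orchestration: signals -> epochs -> PLI -> graphs -> statistics.

A single :class:`RunConfig` drives the whole analysis with reproducible
seeding: the run seed is expanded into per-subject, per-band substreams, so
adding a subject never perturbs another subject's randomness.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import io
from .connectivity import average_epoch_matrices, pli_matrix
from .graphs import (
    DEFAULT_KAPPA,
    DEFAULT_KAPPA_GRID,
    DEFAULT_N_RAND,
    DEFAULT_SWAPS_PER_EDGE,
    metrics_over_thresholds,
)
from .preprocess import (
    BANDS,
    DEFAULT_EPOCH_LENGTH,
    DEFAULT_MIN_EPOCHS,
    RoiTimeSeriesSet,
    SubjectExclusionError,
    bandpass_epochs,
    segment_epochs,
)
from .stats import (
    bonferroni,
    records_to_frame,
    cem_match,
    robust_regression,
    two_sample_t,
    weighted_group_regression,
)
from .synthetic import CohortEffectSpec, generate_cohort

logger = logging.getLogger(__name__)

SRS_SCALES = ["srs_t", "srs_awa", "srs_cog", "srs_com", "srs_mot", "srs_man"]


@dataclass
class RunConfig:
    """Defaults follow the study's analysis choices throughout."""

    signals_path: str | None = None  # HDF5 written by io.write_signals
    metadata_path: str | None = None  # cohort CSV
    synthesis: CohortEffectSpec | None = None  # alternative to the two paths
    bands: tuple[str, ...] = tuple(BANDS)
    epoch_length: float = DEFAULT_EPOCH_LENGTH
    min_epochs: int = DEFAULT_MIN_EPOCHS
    kappas: tuple[float, ...] = DEFAULT_KAPPA_GRID
    primary_kappa: float = DEFAULT_KAPPA
    n_rand: int = DEFAULT_N_RAND
    swaps_per_edge: int = DEFAULT_SWAPS_PER_EDGE
    seed: int = 0
    match_var: str = "mps"
    alpha: float = 0.05
    n_comparisons: int = 5  # Bonferroni over the five bands / five sub-scales
    symptom_band: str = "beta"  # symptom regressions restricted to this band
    symptom_group: str = "ASD-like"  # and to this group (floor effect in TD)
    output_dir: str = "plinet_run"

    def config_hash(self) -> str:
        d = asdict(self)
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def compute_metric_table(
    signals: list[RoiTimeSeriesSet],
    config: RunConfig,
) -> tuple[pd.DataFrame, list[dict]]:
    """Per-(subject, band, kappa) graph metrics; excluded subjects logged.

    Subjects with fewer than ``min_epochs`` epochs are skipped (recorded in
    the returned exclusion list), mirroring the minimum-recording rule.
    """
    ss = np.random.SeedSequence(config.seed)
    rows, exclusions = [], []
    for ts in signals:
        sid_key = int.from_bytes(
            hashlib.sha256(ts.subject_id.encode()).digest()[:4], "little"
        )
        subject_ss = np.random.SeedSequence(entropy=ss.entropy, spawn_key=(sid_key,))
        try:
            epochs = segment_epochs(ts, config.epoch_length, config.min_epochs)
        except SubjectExclusionError as err:
            logger.warning("excluding %s: %s", ts.subject_id, err)
            exclusions.append(
                {"subject_id": ts.subject_id, "reason": str(err)}
            )
            continue
        for band, band_ss in zip(config.bands, subject_ss.spawn(len(config.bands))):
            bs = bandpass_epochs(
                epochs, band, ts.fs, subject_id=ts.subject_id,
                epoch_length=config.epoch_length,
            )
            avg = average_epoch_matrices(pli_matrix(bs, min_epochs=config.min_epochs))
            for ms in metrics_over_thresholds(
                avg, config.kappas, n_rand=config.n_rand,
                swaps_per_edge=config.swaps_per_edge, seed=band_ss,
            ):
                rows.append(
                    {
                        "subject_id": ts.subject_id,
                        "band": band,
                        "kappa": ms.kappa,
                        "cc": ms.cc,
                        "cpl": ms.cpl,
                        "cc_norm": ms.cc_norm,
                        "cpl_norm": ms.cpl_norm,
                        "sw": ms.sw,
                        "n_rand": ms.n_rand,
                        "seed": config.seed,
                    }
                )
    return pd.DataFrame(rows), exclusions


def _fit_row(fit, term: str) -> dict:
    return {
        "coeff": fit.coefficients[term],
        "se": fit.standard_errors[term],
        "t": fit.t_values[term],
        "p": fit.p_values[term],
        "ci_low": fit.conf_int.loc[term, "low"],
        "ci_high": fit.conf_int.loc[term, "high"],
        "r_squared": fit.r_squared,
    }


def group_statistics(
    metric_df: pd.DataFrame, meta: pd.DataFrame, config: RunConfig
) -> dict:
    """The group-analysis battery on a finished metric table.

    Order mirrors the analysis design: unmatched one-tailed t-tests of SW
    per band at the primary threshold, CEM on the matching variable, then
    CEM-weighted regressions of each metric on the group indicator for
    every band and threshold, with Bonferroni control over the five bands.
    Symptom regressions (HC1 robust) run within the configured group and
    band, SRS-T first and then the five sub-scales under Bonferroni.
    """
    df = metric_df.merge(meta, on="subject_id", how="inner")

    # --- unmatched one-tailed t-tests per band at the primary threshold
    trows = []
    at_k = df[np.isclose(df["kappa"], config.primary_kappa)]
    for band in config.bands:
        sub = at_k[at_k["band"] == band]
        a = sub.loc[sub["group"] == "ASD-like", "sw"]
        b = sub.loc[sub["group"] == "TD-like", "sw"]
        t, dof, p = two_sample_t(a, b, tail="one_lower")
        trows.append({"band": band, "metric": "sw", "t": t, "df": dof, "p": p})
    ttests = pd.DataFrame(trows)
    ttests["significant_bonferroni"] = bonferroni(
        ttests["p"], m=config.n_comparisons, alpha=config.alpha
    )

    # --- CEM on the matching variable (listwise exclusion of missing scores)
    cem = cem_match(meta.dropna(subset=[config.match_var]), match_var=config.match_var)
    weights = (
        meta["subject_id"].map(cem.weights).fillna(0.0).to_numpy()
    )
    wmap = pd.Series(weights, index=meta["subject_id"])

    # --- CEM-weighted group regressions per band, metric, kappa
    rrows = []
    for (band, kappa), sub in df.groupby(["band", "kappa"], sort=True):
        for metric in ("sw", "cc", "cpl"):
            fit = weighted_group_regression(
                sub[metric],
                (sub["group"] == "ASD-like").astype(float),
                sub["subject_id"].map(wmap).to_numpy(),
            )
            rrows.append(
                {"band": band, "kappa": kappa, "metric": metric}
                | _fit_row(fit, "group")
            )
    wls = pd.DataFrame(rrows)
    prim = wls[
        np.isclose(wls["kappa"], config.primary_kappa) & (wls["metric"] == "sw")
    ]
    sig = dict(
        zip(
            prim["band"],
            bonferroni(prim["p"], m=config.n_comparisons, alpha=config.alpha),
        )
    )
    wls["significant_bonferroni"] = [
        sig.get(b, False)
        if (m == "sw" and np.isclose(k, config.primary_kappa))
        else False
        for b, k, m in zip(wls["band"], wls["kappa"], wls["metric"])
    ]

    # --- symptom regressions: HC1 robust, within the symptom group/band
    srows = []
    sub = df[
        np.isclose(df["kappa"], config.primary_kappa)
        & (df["band"] == config.symptom_band)
        & (df["group"] == config.symptom_group)
    ]
    for scale in SRS_SCALES + ["ados_sc"]:
        pair = sub[["sw", scale]].dropna()
        if len(pair) < 3 or pair[scale].nunique() < 2:
            continue
        fit = robust_regression(pair["sw"], pair[scale], x_name=scale)
        srows.append(
            {"scale": scale, "n": len(pair), "f": fit.f_statistic}
            | _fit_row(fit, scale)
        )
    symptom = pd.DataFrame(srows)
    if len(symptom):
        # SRS-T at plain alpha; the five sub-scales under Bonferroni
        sig_flags = []
        for _, row in symptom.iterrows():
            m = config.n_comparisons if row["scale"] in SRS_SCALES[1:] else 1
            sig_flags.append(bool(row["p"] < config.alpha / m))
        symptom["significant"] = sig_flags

    return {
        "ttests": ttests,
        "cem": cem,
        "weights": wmap,
        "weighted_regressions": wls,
        "symptom_regressions": symptom,
    }


def summarize_thresholds(metric_df: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Per-(band, kappa, group, metric) means with 95% t-based CIs.

    Single-subject groups get NaN CI bounds (flagged via ``ci_defined``).
    """
    df = metric_df.merge(meta[["subject_id", "group"]], on="subject_id", how="inner")
    if df["group"].isna().any() or len(df) == 0:
        raise ValueError("missing group labels")
    rows = []
    for (band, kappa, group), sub in df.groupby(["band", "kappa", "group"], sort=True):
        for metric in ("sw", "cc", "cpl"):
            v = sub[metric].to_numpy(float)
            mean = v.mean()
            if len(v) >= 2:
                sem = v.std(ddof=1) / np.sqrt(len(v))
                h = sps.t.ppf(0.975, len(v) - 1) * sem
                lo, hi = mean - h, mean + h
            else:
                lo = hi = float("nan")
            rows.append(
                {
                    "band": band, "kappa": kappa, "group": group,
                    "metric": metric, "mean": mean, "ci_low": lo,
                    "ci_high": hi, "n": len(v),
                    "ci_defined": len(v) >= 2,
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis and write its artifacts to ``output_dir``.

    Returns a dict with the metric table, statistics tables, threshold
    summary and the run summary.  Deterministic given ``config.seed``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.synthesis is not None:
        signals, records = generate_cohort(config.synthesis)
        meta = records_to_frame(records)
    elif config.signals_path and config.metadata_path:
        signals = io.read_signals(config.signals_path)
        meta = io.read_metadata(config.metadata_path)
    else:
        raise ValueError("config needs either synthesis or signals+metadata paths")

    metric_df, exclusions = compute_metric_table(signals, config)
    if metric_df.empty:
        raise ValueError("no subjects survived epoch screening")
    meta = meta[meta["subject_id"].isin(metric_df["subject_id"])].reset_index(drop=True)

    stats = group_statistics(metric_df, meta, config)
    summary_df = summarize_thresholds(metric_df, meta)

    metric_df.to_csv(out / "metrics.csv", index=False)
    meta.to_csv(out / "metadata.csv", index=False)
    stats["ttests"].to_csv(out / "group_ttests.csv", index=False)
    stats["weighted_regressions"].to_csv(out / "group_regressions.csv", index=False)
    stats["symptom_regressions"].to_csv(out / "symptom_regressions.csv", index=False)
    summary_df.to_csv(out / "threshold_summary.csv", index=False)

    run_summary = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "bands": list(config.bands),
        "kappas": [float(k) for k in config.kappas],
        "n_rand": config.n_rand,
        "swaps_per_edge": config.swaps_per_edge,
        "n_subjects": int(meta.shape[0]),
        "exclusions": exclusions,
        "cem": {
            "l1_before": stats["cem"].l1_before,
            "l1_after": stats["cem"].l1_after,
            "n_matched_treated": stats["cem"].n_matched_treated,
            "n_matched_control": stats["cem"].n_matched_control,
        },
    }
    (out / "run_summary.json").write_text(json.dumps(run_summary, indent=2))

    return {
        "metrics": metric_df,
        "metadata": meta,
        "stats": stats,
        "threshold_summary": summary_df,
        "run_summary": run_summary,
        "exclusions": exclusions,
    }
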