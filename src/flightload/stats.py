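"""Metric assembly and workload correlations.

Every session reduces to one row of cognitive-load metrics (two pupil
variabilities, fixation rate and duration, NNI, TLI, TEI) plus the
inceptor workload baseline (duty cycle, aggressiveness, PIW).  Each
physiological metric is then associated with PIW two ways:

* **Pearson correlation** across all rows, treating the session rows as
  independent observations (df = n - 2);
* **repeated-measures correlation (rmcorr)** — the common within-
  participant association, estimated by analysis of covariance with
  participant-specific intercepts and one shared slope
  (df = N_obs - k_participants - 1).  rmcorr is immune to between-
  participant offsets that can inflate or mask a pooled Pearson r.

Missing cells (e.g. an unusable EEG stream) are flagged NaN and dropped
pairwise per correlation, never silently zeroed.  p-values are reported
descriptively with no multiple-testing correction.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sstats

from .eeg import compute_eeg_metrics
from .inceptor import compute_inceptor_metrics
from .ocular import compute_ocular_metrics
from .synthetic import SessionData

logger = logging.getLogger(__name__)

__all__ = [
    "PHYSIO_METRICS",
    "CorrelationResult",
    "build_metric_table",
    "pearson",
    "rmcorr",
    "correlate_with_piw",
    "pilot_variability",
    "format_report",
]

#: The seven physiological metrics correlated against PIW, report order.
PHYSIO_METRICS: tuple[str, ...] = (
    "stddev_pd_left",
    "stddev_pd_right",
    "fixation_rate",
    "mean_fixation_duration",
    "nni",
    "tli",
    "tei",
)

METRIC_COLUMNS: tuple[str, ...] = PHYSIO_METRICS + (
    "duty_cycle",
    "aggressiveness",
    "piw",
)


@dataclasses.dataclass
class CorrelationResult:
    """Pearson and repeated-measures association of one metric with PIW."""

    metric: str
    r: float
    df: int
    p: float
    r_rm: float
    df_rm: int
    p_rm: float


def build_metric_table(sessions: list[SessionData]) -> pd.DataFrame:
    """One row of metrics per (participant, condition) session.

    A stream that fails to process leaves its metrics NaN in that row with
    a logged warning; the other streams' metrics survive.
    """
    rows = []
    seen: set[tuple[int, int]] = set()
    for s in sessions:
        key = (s.participant, s.condition)
        if key in seen:
            raise ValueError(f"duplicate session for participant/condition {key}")
        seen.add(key)
        row: dict = {"participant": s.participant, "condition": s.condition}
        try:
            row.update(compute_ocular_metrics(s.gaze))
        except (ValueError, KeyError) as exc:
            logger.warning("ocular metrics failed for %s: %s", key, exc)
            row.update({m: np.nan for m in PHYSIO_METRICS[:5]})
        try:
            row.update(compute_eeg_metrics(s.eeg))
        except (ValueError, KeyError) as exc:
            logger.warning("EEG metrics failed for %s: %s", key, exc)
            row.update({"tli": np.nan, "tei": np.nan})
        try:
            row.update(compute_inceptor_metrics(s.stick))
        except (ValueError, KeyError) as exc:
            logger.warning("inceptor metrics failed for %s: %s", key, exc)
            row.update({"duty_cycle": np.nan, "aggressiveness": np.nan, "piw": np.nan})
        rows.append(row)
    cols = ["participant", "condition", *METRIC_COLUMNS]
    return pd.DataFrame(rows)[cols]


def pearson(x, y) -> tuple[float, int, float]:
    """Product-moment correlation with pairwise NaN removal.

    Returns ``(r, df, p)`` with df = n - 2 and a two-sided p-value; a
    zero-variance input yields ``(nan, df, nan)`` (flagged undefined).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, got {n}")
    df = n - 2
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), df, float("nan")
    r, p = sstats.pearsonr(x, y)
    return float(r), df, float(p)


def rmcorr(subjects, x, y) -> tuple[float, int, float]:
    """Repeated-measures correlation (ANCOVA with subject intercepts).

    Subjects contributing fewer than 2 complete observations are dropped
    with a warning.  Returns ``(r_rm, df, p)`` with
    df = N_obs - k_subjects - 1.
    """
    df_in = pd.DataFrame({"subject": np.asarray(subjects), "x": x, "y": y}).dropna()
    counts = df_in.groupby("subject").size()
    small = counts[counts < 2].index
    if len(small):
        logger.warning(
            "rmcorr: dropping %d subject(s) with < 2 observations", len(small)
        )
        df_in = df_in[~df_in["subject"].isin(small)]
    if df_in["subject"].nunique() < 2:
        raise ValueError("rmcorr needs >= 2 subjects with >= 2 observations each")
    model = smf.ols("y ~ C(subject) + x", data=df_in).fit()
    table = sm.stats.anova_lm(model, typ=3)
    ss_measure = float(table.loc["x", "sum_sq"])
    ss_error = float(table.loc["Residual", "sum_sq"])
    dof = int(table.loc["Residual", "df"])  # N_obs - k_subjects - 1
    slope = float(model.params["x"])
    r_rm = float(np.sign(slope) * np.sqrt(ss_measure / (ss_measure + ss_error)))
    if ss_error == 0.0:
        return r_rm, dof, 0.0
    p = float(table.loc["x", "PR(>F)"])
    return r_rm, dof, p


def correlate_with_piw(
    table: pd.DataFrame, metrics: tuple[str, ...] = PHYSIO_METRICS
) -> pd.DataFrame:
    """Pearson + rmcorr of each physiological metric against PIW."""
    out = []
    for metric in metrics:
        r, df, p = pearson(table[metric], table["piw"])
        r_rm, df_rm, p_rm = rmcorr(table["participant"], table[metric], table["piw"])
        out.append(
            dataclasses.asdict(
                CorrelationResult(metric, r, df, p, r_rm, df_rm, p_rm)
            )
        )
    return pd.DataFrame(out)


def pilot_variability(table: pd.DataFrame) -> pd.DataFrame:
    """Per-participant sample std of each metric across conditions.

    Captures how consistently each pilot's cognitive-load scores respond
    to changing task conditions; participants with fewer than 2 usable
    conditions are NaN-flagged.
    """
    cols = list(METRIC_COLUMNS)
    grouped = table.groupby("participant")[cols]
    sd = grouped.std(ddof=1)
    counts = grouped.count()
    sd = sd.where(counts >= 2)
    return sd


def run_pipeline(
    config: str | None = None,
    session_dir: str | None = None,
    outdir: str = "results",
    seed: int | None = None,
) -> dict:
    """End-to-end study analysis.

    Either generates the synthetic study described by ``config`` (YAML; the
    default design when omitted) or loads session CSVs from
    ``session_dir``, computes the per-session metric table, the
    correlation report against PIW and the per-pilot variability table, and
    writes all three under ``outdir``.  Deterministic for a fixed seed.

    Returns a dict with the three DataFrames and the output paths.
    """
    from pathlib import Path

    from . import io as fio
    from .synthetic import EffectProfile, StudyDesign, generate_study

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    if session_dir is not None:
        logger.info("loading sessions from %s", session_dir)
        sessions = fio.load_study(session_dir)
    else:
        if config is not None:
            design, effects = fio.load_config(config)
        else:
            design, effects = StudyDesign(), EffectProfile()
        if seed is not None:
            design = dataclasses.replace(design, seed=seed)
        logger.info(
            "generating synthetic study: %d participants x %d conditions, seed %d",
            design.n_participants, design.n_conditions, design.seed,
        )
        sessions = generate_study(design, effects)
    logger.info("computing metric table for %d sessions", len(sessions))
    table = build_metric_table(sessions)
    corr = correlate_with_piw(table)
    var = pilot_variability(table)

    table_path = out / "metric_table.csv"
    corr_path = out / "correlations.csv"
    var_path = out / "pilot_variability.csv"
    report_path = out / "report.txt"
    table.to_csv(table_path, index=False)
    corr.to_csv(corr_path, index=False)
    var.to_csv(var_path)
    report_path.write_text(format_report(corr) + "\n")
    logger.info("wrote %s, %s, %s", table_path, corr_path, var_path)
    return {
        "table": table,
        "correlations": corr,
        "variability": var,
        "paths": {
            "table": table_path,
            "correlations": corr_path,
            "variability": var_path,
            "report": report_path,
        },
    }


def format_report(corr: pd.DataFrame) -> str:
    """Human-readable comparison table of Pearson r and rmcorr per metric."""
    lines = [
        f"{'Cognitive load parameter':<28}{'r':>9}{'df':>5}{'p':>11}"
        f"{'r_rm':>9}{'df_rm':>7}{'p_rm':>11}",
        "-" * 80,
    ]
    for _, row in corr.iterrows():
        lines.append(
            f"{row['metric']:<28}{row['r']:>9.3f}{int(row['df']):>5}"
            f"{row['p']:>11.2e}{row['r_rm']:>9.3f}{int(row['df_rm']):>7}"
            f"{row['p_rm']:>11.2e}"
        )
    return "\n".join(lines)
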