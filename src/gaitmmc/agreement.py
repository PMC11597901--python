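"""Method-agreement and test–retest statistics.

Implements the validation statistics used to compare a markerless gait
system against a marker-based reference and against itself across sessions:

* waveform RMSE (mean ± SD across participants) and Lin's concordance
  correlation coefficient (CCC) with Fisher-z asymptotic 95 % CIs;
* Pearson r, Bland–Altman bias and limits of agreement on discrete
  parameters (max / min / ROM);
* ICC(2,1) — two-way random effects, absolute agreement, single measures —
  with F-based CIs, and the derived SEM and MDC;
* the constant-offset correction that subtracts the mean waveform
  difference between systems per participant-session.

All covariances use n−1 denominators.  Degenerate inputs (zero variance)
raise rather than silently returning NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from gaitmmc.types import StatsConfig, ValidationError

# interpretation bands: (upper bound, label), scanned in order
PEARSON_BANDS = [(0.30, "negligent"), (0.50, "low"), (0.70, "moderate"), (0.90, "high"), (1.01, "very high")]
LCC_BANDS = [(0.90, "poor"), (0.95, "moderate"), (0.99, "substantial"), (1.01, "almost perfect")]
ICC_BANDS = [(0.50, "poor"), (0.75, "moderate"), (0.90, "good"), (1.01, "excellent")]


def interpret(value: float, bands: list[tuple[float, str]]) -> str:
    """Map a coefficient to its interpretation label."""
    for upper, label in bands:
        if value < upper:
            return label
    return bands[-1][1]


# ---------------------------------------------------------------------------
# waveform statistics


def rmse_waveforms(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Per-participant waveform RMSE; returns (mean, SD) across participants.

    ``a`` and ``b`` are ``(n_participants, n_points)`` stacks of mean gait
    cycles on a common phase grid.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.shape != b.shape:
        raise ValidationError(f"phase-grid mismatch: {a.shape} vs {b.shape}")
    per = np.sqrt(np.mean((a - b) ** 2, axis=1))
    sd = float(per.std(ddof=1)) if per.size > 1 else 0.0
    return float(per.mean()), sd


def lin_ccc(x, y, z_coverage: float = 1.96) -> tuple[float, float, float]:
    """Lin's concordance correlation coefficient with an asymptotic CI.

    CCC = 2·s_xy / (s_x² + s_y² + (x̄−ȳ)²) with n−1 denominators; the CI uses
    the Fisher z-transform with Lin's (1989) asymptotic standard error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3 or y.size != n:
        raise ValidationError("need two equal-length vectors with n >= 3")
    sx2 = x.var(ddof=1)
    sy2 = y.var(ddof=1)
    if sx2 == 0 and sy2 == 0:
        raise ValidationError("concordance undefined: both inputs have zero variance")
    sxy = np.cov(x, y, ddof=1)[0, 1]
    d = x.mean() - y.mean()
    ccc = 2 * sxy / (sx2 + sy2 + d**2)
    if sx2 == 0 or sy2 == 0 or abs(ccc) >= 1 - 1e-15:
        return float(ccc), float(ccc), float(ccc)
    r = sxy / np.sqrt(sx2 * sy2)
    u = d / (sx2 * sy2) ** 0.25
    if abs(r) < 1e-12:
        return float(ccc), float("nan"), float("nan")
    c2 = ccc**2
    se2 = (
        (1 - r**2) * c2 / ((1 - c2) * r**2)
        + 2 * ccc**3 * (1 - ccc) * u**2 / (r * (1 - c2) ** 2)
        - ccc**4 * u**4 / (2 * r**2 * (1 - c2) ** 2)
    ) / (n - 2)
    se = np.sqrt(max(se2, 0.0))
    z = np.arctanh(ccc)
    lo, hi = np.tanh(z - z_coverage * se), np.tanh(z + z_coverage * se)
    return float(ccc), float(lo), float(hi)


def pearson(x, y) -> float:
    """Product-moment correlation; zero-variance input is an error."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size != x.size:
        raise ValidationError("need two equal-length vectors with n >= 3")
    if x.var() == 0 or y.var() == 0:
        raise ValidationError("correlation undefined: zero variance")
    return float(stats.pearsonr(x, y).statistic)


# ---------------------------------------------------------------------------
# discrete-parameter agreement


@dataclass
class PairedParams:
    """Paired per-participant values of one discrete parameter from two systems."""

    a: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.a.shape != self.b.shape or self.a.ndim != 1:
            raise ValidationError("paired vectors must be 1-D and equal length")

    @property
    def n(self) -> int:
        return self.a.size


def bland_altman(p: PairedParams, z: float = 1.96) -> tuple[float, float, float]:
    """Bland–Altman bias and limits of agreement, ``bias ± z·SD(d)``, d = A−B."""
    if p.n < 2:
        raise ValidationError("need at least two pairs")
    d = p.a - p.b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, bias - z * sd, bias + z * sd


def icc_2_1(data: np.ndarray, alpha: float = 0.05) -> tuple[float, float, float]:
    """ICC(2,1): two-way random effects, absolute agreement, single measures.

    ``data`` is ``(n_subjects, k_raters)``.  The point estimate comes from
    the two-way ANOVA mean squares; the CI is the F-based interval of
    McGraw & Wong.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValidationError("data must be (n_subjects, k) 2-D")
    n, k = data.shape
    if n < 3 or k < 2:
        raise ValidationError("need n >= 3 subjects and k >= 2 measurements")
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((data - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom <= 0:
        raise ValidationError("ICC undefined: zero total variance")
    icc = (msr - mse) / denom
    if mse <= 0 and msc <= 1e-300:  # perfect agreement
        return float(icc), float(icc), float(icc)
    a_ = (k * icc) / (n * (1 - icc)) if icc < 1 else np.inf
    b_ = 1 + (k * icc * (n - 1)) / (n * (1 - icc)) if icc < 1 else np.inf
    if not np.isfinite(a_):
        return float(icc), float(icc), float(icc)
    with np.errstate(all="ignore"):
        v = (a_ * msc + b_ * mse) ** 2 / (
            (a_ * msc) ** 2 / (k - 1) + (b_ * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f1 = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lower = n * (msr - f1 * mse) / (f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
        upper = n * (f2 * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f2 * msr)
    if np.isfinite(lower):
        lower = max(-1.0, min(lower, icc))
    if np.isfinite(upper):
        upper = min(1.0, max(upper, icc))
    return float(icc), float(lower), float(upper)


def sem_from_icc(sd_pooled: float, icc: float) -> float:
    """Standard error of measurement, SEM = SD·√(1−ICC)."""
    if sd_pooled < 0:
        raise ValidationError("sd must be >= 0")
    if not 0 <= icc <= 1:
        raise ValidationError("icc must lie in [0, 1] for SEM")
    return float(sd_pooled * np.sqrt(1 - icc))


def mdc_from_sem(sem: float, convention: str = "z_over_sqrt2", z: float = 1.96) -> float:
    """Minimal detectable change from the SEM.

    ``"z_over_sqrt2"``: MDC = z·SEM/√2 (≈1.386·SEM), the arithmetic several
    published gait-reliability tables follow; ``"z_times_sqrt2"``: the
    conventional MDC95 = z·√2·SEM.
    """
    if sem < 0:
        raise ValidationError("sem must be >= 0")
    if convention == "z_over_sqrt2":
        return float(z * sem / np.sqrt(2))
    if convention == "z_times_sqrt2":
        return float(z * np.sqrt(2) * sem)
    raise ValidationError(f"unknown MDC convention {convention!r}")


def offset_correct(mmc: np.ndarray, ref: np.ndarray) -> tuple[np.ndarray, float]:
    """Subtract the mean waveform difference between systems.

    Returns ``(corrected, offset)`` with ``offset = mean(mmc − ref)`` over
    the phase grid; the corrected waveform has exactly zero mean residual
    and an unchanged range of motion.
    """
    mmc = np.asarray(mmc, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if mmc.shape != ref.shape:
        raise ValidationError("phase-grid mismatch between systems")
    offset = float(np.mean(mmc - ref))
    return mmc - offset, offset


# ---------------------------------------------------------------------------
# report assembly


@dataclass
class TrialSummary:
    """Per-trial, per-joint processed outputs used by the report builders."""

    participant_id: str
    session: int
    speed: float
    joint: str
    max: float
    min: float
    rom: float
    mean_cycle: np.ndarray


def _index(summaries: list[TrialSummary]):
    return {(s.participant_id, s.session, s.speed, s.joint): s for s in summaries}


def reliability_report(
    summaries: list[TrialSummary],
    cfg: StatsConfig | None = None,
) -> "pd.DataFrame":
    """Test–retest reliability per joint × speed from a two-session study.

    ICC(2,1)/SEM/MDC on max, min and ROM (SD pooled over both sessions'
    measurements); waveform RMSE (mean, SD across participants) between the
    two sessions' mean cycles; CCC on the pooled waveform points.
    """
    import pandas as pd

    cfg = cfg or StatsConfig()
    by_key = _index(summaries)
    joints = sorted({s.joint for s in summaries})
    speeds = sorted({s.speed for s in summaries})
    participants = sorted({s.participant_id for s in summaries})
    rows = []
    for joint in joints:
        for speed in speeds:
            pids = [
                p
                for p in participants
                if (p, 1, speed, joint) in by_key and (p, 2, speed, joint) in by_key
            ]
            if len(pids) < 3:
                raise ValidationError(f"fewer than 3 participants with both sessions ({joint}, {speed})")
            s1 = [by_key[(p, 1, speed, joint)] for p in pids]
            s2 = [by_key[(p, 2, speed, joint)] for p in pids]
            row = {"joint": joint, "speed": speed, "n": len(pids)}
            for param in ("max", "min", "rom"):
                mat = np.array(
                    [[getattr(a, param), getattr(b, param)] for a, b in zip(s1, s2)]
                )
                icc, lo, hi = icc_2_1(mat)
                sd_pooled = float(mat.ravel().std(ddof=1))
                sem = sem_from_icc(sd_pooled, min(max(icc, 0.0), 1.0))
                mdc = mdc_from_sem(sem, cfg.mdc_convention, cfg.z_coverage)
                row.update(
                    {
                        f"icc_{param}": icc,
                        f"icc_{param}_ci_low": lo,
                        f"icc_{param}_ci_high": hi,
                        f"icc_{param}_label": interpret(icc, ICC_BANDS),
                        f"sem_{param}": sem,
                        f"mdc_{param}": mdc,
                    }
                )
            w1 = np.array([s.mean_cycle for s in s1])
            w2 = np.array([s.mean_cycle for s in s2])
            rmse_mean, rmse_sd = rmse_waveforms(w1, w2)
            lcc, lcc_lo, lcc_hi = lin_ccc(w1.ravel(), w2.ravel(), cfg.z_coverage)
            row.update(
                {
                    "rmse_mean": rmse_mean,
                    "rmse_sd": rmse_sd,
                    "lcc": lcc,
                    "lcc_ci_low": lcc_lo,
                    "lcc_ci_high": lcc_hi,
                    "lcc_label": interpret(lcc, LCC_BANDS),
                }
            )
            rows.append(row)
    return pd.DataFrame(rows)


def accuracy_report(
    mmc: list[TrialSummary],
    ref: list[TrialSummary],
    corrected: bool = False,
    cfg: StatsConfig | None = None,
) -> "pd.DataFrame":
    """Agreement of the markerless system against the reference, per joint × speed.

    Bland–Altman bias/LoA and Pearson r on max/min/ROM; waveform RMSE and
    CCC.  With ``corrected=True`` the constant-offset correction is applied
    per participant-session before every statistic (ROM is shift-invariant
    and therefore unchanged).
    """
    import pandas as pd

    cfg = cfg or StatsConfig()
    ref_by_key = _index(ref)
    joints = sorted({s.joint for s in mmc})
    speeds = sorted({s.speed for s in mmc})
    rows = []
    for joint in joints:
        for speed in speeds:
            pairs = []
            for s in mmc:
                if s.joint != joint or s.speed != speed:
                    continue
                key = (s.participant_id, s.session, s.speed, s.joint)
                if key not in ref_by_key:
                    raise ValidationError(f"no reference trial paired with {key}")
                pairs.append((s, ref_by_key[key]))
            if len(pairs) < 3:
                raise ValidationError(f"fewer than 3 paired trials ({joint}, {speed})")
            a_params = {p: [] for p in ("max", "min", "rom")}
            b_params = {p: [] for p in ("max", "min", "rom")}
            wa, wb = [], []
            for m, r in pairs:
                m_cycle = m.mean_cycle
                shift = 0.0
                if corrected:
                    m_cycle, shift = offset_correct(m.mean_cycle, r.mean_cycle)
                wa.append(m_cycle)
                wb.append(r.mean_cycle)
                a_params["max"].append(m.max - shift)
                a_params["min"].append(m.min - shift)
                a_params["rom"].append(m.rom)
                b_params["max"].append(r.max)
                b_params["min"].append(r.min)
                b_params["rom"].append(r.rom)
            row = {"joint": joint, "speed": speed, "n": len(pairs)}
            for param in ("max", "min", "rom"):
                p = PairedParams(np.array(a_params[param]), np.array(b_params[param]))
                bias, lo, hi = bland_altman(p, cfg.z_coverage)
                r_val = pearson(p.a, p.b)
                row.update(
                    {
                        f"bias_{param}": bias,
                        f"loa_low_{param}": lo,
                        f"loa_high_{param}": hi,
                        f"r_{param}": r_val,
                        f"r_{param}_label": interpret(abs(r_val), PEARSON_BANDS),
                    }
                )
            wa = np.array(wa)
            wb = np.array(wb)
            rmse_mean, rmse_sd = rmse_waveforms(wa, wb)
            lcc, lcc_lo, lcc_hi = lin_ccc(wa.ravel(), wb.ravel(), cfg.z_coverage)
            row.update(
                {
                    "rmse_mean": rmse_mean,
                    "rmse_sd": rmse_sd,
                    "lcc": lcc,
                    "lcc_ci_low": lcc_lo,
                    "lcc_ci_high": lcc_hi,
                    "lcc_label": interpret(lcc, LCC_BANDS),
                }
            )
            rows.append(row)
    return pd.DataFrame(rows)
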