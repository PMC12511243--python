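"""Non-fiducial feature extraction.

Nineteen whole-segment statistics are computed on each of the three
channels (PPG, VPG, APG), giving a 57-element feature vector per segment.
None of them requires locating landmarks on the waveform:

* distribution statistics: mean, median, standard deviation, variance,
  interquartile range, skewness, kurtosis;
* zero-crossing rate and Shannon entropy;
* mean/variance/skewness/kurtosis/IQR of the instantaneous energy
  ``E(n) = x(n)^2``;
* the same five statistics of the Kaiser-Teager energy
  ``psi(n) = x(n)^2 - x(n-1) x(n+1)``.

Conventions (they matter for reproducibility and are fixed here):
population (divide-by-n) central moments; kurtosis non-excess (a normal
sample gives ~3); skewness/kurtosis of a constant signal defined as 0;
linear-interpolation (type-7) quantiles for the IQR; entropy from a
16-bin equal-width histogram spanning [min, max].
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .population import PPGRecording
from .preprocess import SegmentBundle, condition

__all__ = [
    "STATS",
    "CHANNELS",
    "METADATA_COLUMNS",
    "feature_names",
    "basic_stats",
    "zcr",
    "shannon_entropy",
    "energy_series",
    "kte_series",
    "stats_of_series",
    "extract_features",
    "build_feature_table",
    "feature_columns",
]

#: Statistic labels, in the fixed output order.
STATS = (
    "mu", "eta", "sigma", "sigma2", "IQR", "skew", "kurt", "ZCR", "H",
    "E_mu", "E_sigma2", "E_skew", "E_kurt", "E_IQR",
    "KTE_mu", "KTE_sigma2", "KTE_skew", "KTE_kurt", "KTE_IQR",
)

CHANNELS = ("PPG", "VPG", "APG")

METADATA_COLUMNS = ("subject_id", "segment_index", "sbp_ref", "dbp_ref", "category")

ENTROPY_BINS = 16


def feature_names() -> list[str]:
    """The 57 feature names, channel-major: ``mu(PPG)`` ... ``KTE_IQR(APG)``."""
    return [f"{stat}({ch})" for ch in CHANNELS for stat in STATS]


def _iqr(x: np.ndarray) -> float:
    q1, q3 = np.percentile(x, [25, 75])  # linear-interpolation quantiles
    return float(q3 - q1)


def basic_stats(x: np.ndarray) -> tuple[float, float, float, float, float, float, float]:
    """(mean, median, sd, variance, IQR, skewness, kurtosis) of a sequence.

    Population convention throughout; for a constant input the sd and
    variance are 0 and skewness/kurtosis are reported as 0.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 4:
        raise ValueError("need at least 4 samples")
    mu = float(np.mean(x))
    eta = float(np.median(x))
    d = x - mu
    sigma2 = float(np.mean(d**2))
    sigma = float(np.sqrt(sigma2))
    if sigma == 0.0:
        skew = kurt = 0.0
    else:
        skew = float(np.mean(d**3) / sigma**3)
        kurt = float(np.mean(d**4) / sigma**4)
    return mu, eta, sigma, sigma2, _iqr(x), skew, kurt


def zcr(x: np.ndarray) -> float:
    """Sign-change rate: strict sign flips per adjacent sample pair.

    Zeros carry the previous nonzero sign; leading zeros carry no sign
    and their pairs are not counted.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 samples")
    s = np.sign(x)
    for i in range(1, len(s)):
        if s[i] == 0:
            s[i] = s[i - 1]
    valid = (s[:-1] != 0) & (s[1:] != 0)
    return float(np.count_nonzero(valid & (s[:-1] != s[1:])) / (len(x) - 1))


def shannon_entropy(x: np.ndarray, bins: int = ENTROPY_BINS) -> float:
    """Histogram estimate of Shannon entropy, in bits.

    Equal-width bins spanning [min, max]; ``H = -sum p log2 p`` over the
    occupied bins, so ``0 <= H <= log2(bins)``.  A constant signal
    occupies one bin and has zero entropy.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 samples")
    if x.max() == x.min():
        return 0.0
    counts, _ = np.histogram(x, bins=bins, range=(x.min(), x.max()))
    p = counts[counts > 0] / len(x)
    return float(-np.sum(p * np.log2(p)))


def energy_series(x: np.ndarray) -> np.ndarray:
    """Instantaneous energy ``E(n) = x(n)^2`` (length preserved)."""
    x = np.asarray(x, dtype=float)
    return x**2


def kte_series(x: np.ndarray) -> np.ndarray:
    """Kaiser-Teager energy ``psi(n) = x(n)^2 - x(n-1) x(n+1)``.

    Defined for interior samples only (length n-2, no boundary padding).
    For a pure sinusoid ``sin(Omega n)`` this is the constant
    ``sin^2(Omega)``, jointly sensitive to amplitude and frequency.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 samples for the Teager operator")
    return x[1:-1] ** 2 - x[:-2] * x[2:]


def stats_of_series(series: np.ndarray) -> tuple[float, float, float, float, float]:
    """(mean, variance, skewness, kurtosis, IQR) of a derived series."""
    mu, _eta, _sigma, sigma2, iqr, skew, kurt = basic_stats(series)
    return mu, sigma2, skew, kurt, iqr


def _channel_features(x: np.ndarray) -> list[float]:
    mu, eta, sigma, sigma2, iqr, skew, kurt = basic_stats(x)
    e_mu, e_s2, e_skew, e_kurt, e_iqr = stats_of_series(energy_series(x))
    k_mu, k_s2, k_skew, k_kurt, k_iqr = stats_of_series(kte_series(x))
    return [
        mu, eta, sigma, sigma2, iqr, skew, kurt, zcr(x), shannon_entropy(x),
        e_mu, e_s2, e_skew, e_kurt, e_iqr,
        k_mu, k_s2, k_skew, k_kurt, k_iqr,
    ]


def extract_features(bundle: SegmentBundle) -> dict[str, float]:
    """The 57-element feature vector of one conditioned segment.

    Keys follow the ``STAT(CHANNEL)`` convention in a fixed order;
    all values are finite (degenerate channels fall back to the
    documented degenerate rules rather than producing NaN).
    """
    values: dict[str, float] = {}
    for ch, x in zip(CHANNELS, (bundle.ppg, bundle.vpg, bundle.apg)):
        for stat, v in zip(STATS, _channel_features(x)):
            values[f"{stat}({ch})"] = v
    assert len(values) == 57
    if not all(np.isfinite(list(values.values()))):
        bad = [k for k, v in values.items() if not np.isfinite(v)]
        raise AssertionError(f"non-finite features: {bad}")
    return values


def build_feature_table(
    recordings: list[PPGRecording], **condition_kwargs
) -> pd.DataFrame:
    """Condition every recording and assemble the segment-level feature table.

    Rows are segments; columns are subject_id, segment_index, the 57
    features, sbp_ref, dbp_ref and the AHA category of the subject.
    """
    rows = []
    for rec in recordings:
        for bundle in condition(rec, **condition_kwargs):
            row = {"subject_id": rec.subject_id, "segment_index": bundle.segment_index}
            row.update(extract_features(bundle))
            row.update(
                sbp_ref=rec.sbp_ref, dbp_ref=rec.dbp_ref, category=rec.category
            )
            rows.append(row)
    columns = ["subject_id", "segment_index", *feature_names(),
               "sbp_ref", "dbp_ref", "category"]
    return pd.DataFrame(rows, columns=columns)


def feature_columns(table: pd.DataFrame) -> list[str]:
    """The feature columns of a table, in canonical order."""
    return [c for c in feature_names() if c in table.columns]
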