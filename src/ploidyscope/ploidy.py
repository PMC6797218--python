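"""Ploidy calling against the endothelial diploid standard, and summaries.

Endothelial nuclei are presumed diploid, so the median of their integrated
DNA-stain signal defines normalized value 1.0; every nucleus is expressed on
that scale and classed 2N below the 2N/4N boundary and >=4N at or above it.
The default boundary sqrt(2) is the geometric midpoint of the 2N (1.0) and
4N (2.0) centres, which makes misclassification symmetric under
multiplicative intensity noise; the second boundary 2*sqrt(2) separates 4N
from >=8N when refinement is requested. Boundary ties go to the higher
class.

Per-heart summaries report the nucleation composition of viable
cardiomyocytes, the diploid fraction among mononuclear CMs, and the
mononuclear-diploid percentage (the product of the two), with a >=600-cell
QC rule. Two groups of hearts are compared with an unpaired two-tailed
Student t-test (pooled variance; Welch available).
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.exceptions import NotFittedError

__all__ = [
    "PloidyClassifier", "normalize_to_ec_median", "call_ploidy_class",
    "summarize_heart", "compare_groups", "HeartSummary", "GroupComparison",
    "BOUNDARY_2N_4N", "BOUNDARY_4N_8N",
]

BOUNDARY_2N_4N = math.sqrt(2.0)
BOUNDARY_4N_8N = 2.0 * math.sqrt(2.0)

CALL_COLUMNS = ["nucleus_id", "cell_id", "cell_type", "normalized_intensity",
                "ploidy_class"]


class PloidyClassifier(BaseEstimator):
    """Nuclear DNA-content classifier normalized to the endothelial median.

    ``fit`` learns the diploid standard (the median integrated signal of
    endothelial nuclei, ``ec_median_``); ``transform`` maps integrated
    intensities onto the normalized scale and ``predict`` emits classes.

    Parameters
    ----------
    boundary_2n4n, boundary_4n8n : float
        Class boundaries on the normalized scale; ties assign upward.
    refine_8n : bool
        Report {2N, 4N, >=8N} instead of {2N, >=4N}.
    min_ec : int
        Minimum number of endothelial nuclei required to anchor the
        standard (default 30).
    """

    def __init__(self, boundary_2n4n: float = BOUNDARY_2N_4N,
                 boundary_4n8n: float = BOUNDARY_4N_8N,
                 refine_8n: bool = False, min_ec: int = 30):
        self.boundary_2n4n = boundary_2n4n
        self.boundary_4n8n = boundary_4n8n
        self.refine_8n = refine_8n
        self.min_ec = min_ec

    def fit(self, nuclei: pd.DataFrame, cells: pd.DataFrame):
        """Learn ``ec_median_`` from the endothelial nuclei of one heart."""
        ec_ids = set(cells.loc[cells["type"] == "EC", "cell_id"])
        ec = nuclei[nuclei["cell_id"].isin(ec_ids)]
        if len(ec) < self.min_ec:
            raise ValueError(
                f"only {len(ec)} endothelial nuclei present; "
                f"at least {self.min_ec} required to anchor the diploid standard")
        median = float(ec["integrated_dapi"].median())
        if median <= 0:
            raise ValueError("endothelial median intensity is not positive")
        self.ec_median_ = median
        self.n_ec_ = int(len(ec))
        return self

    def _check_fitted(self):
        if not hasattr(self, "ec_median_"):
            raise NotFittedError("PloidyClassifier is not fitted")

    def transform(self, intensities) -> np.ndarray:
        """Normalized intensities: integrated signal / endothelial median."""
        self._check_fitted()
        x = np.asarray(intensities, dtype=np.float64)
        return x / self.ec_median_

    def predict(self, intensities) -> np.ndarray:
        self._check_fitted()
        return call_ploidy_class(self.transform(intensities),
                                 boundary_2n4n=self.boundary_2n4n,
                                 boundary_4n8n=self.boundary_4n8n,
                                 refine_8n=self.refine_8n)

    def calls(self, nuclei: pd.DataFrame, cells: pd.DataFrame) -> pd.DataFrame:
        """Per-nucleus call table (CM and EC nuclei both emitted)."""
        self._check_fitted()
        typed = nuclei.merge(cells[["cell_id", "type"]], on="cell_id",
                             how="inner")
        out = pd.DataFrame({
            "nucleus_id": typed["nucleus_id"],
            "cell_id": typed["cell_id"],
            "cell_type": typed["type"],
            "normalized_intensity": self.transform(typed["integrated_dapi"]),
        })
        out["ploidy_class"] = call_ploidy_class(
            out["normalized_intensity"].to_numpy(),
            boundary_2n4n=self.boundary_2n4n,
            boundary_4n8n=self.boundary_4n8n, refine_8n=self.refine_8n)
        return out


def call_ploidy_class(normalized, boundary_2n4n: float = BOUNDARY_2N_4N,
                      boundary_4n8n: float = BOUNDARY_4N_8N,
                      refine_8n: bool = False):
    """Class from normalized intensity; boundary values assign upward."""
    x = np.asarray(normalized, dtype=np.float64)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    if (x <= 0).any():
        raise ValueError("normalized intensities must be positive")
    if refine_8n:
        out = np.where(x < boundary_2n4n, "2N",
                       np.where(x < boundary_4n8n, "4N", ">=8N"))
    else:
        out = np.where(x < boundary_2n4n, "2N", ">=4N")
    return out[0] if scalar else out


def normalize_to_ec_median(nuclei: pd.DataFrame, cells: pd.DataFrame,
                           min_ec: int = 30, **kwargs) -> pd.DataFrame:
    """Functional wrapper: fit the classifier and emit the call table."""
    clf = PloidyClassifier(min_ec=min_ec, **kwargs)
    return clf.fit(nuclei, cells).calls(nuclei, cells)


@dataclass
class HeartSummary:
    """Nucleation/ploidy composition of one heart's viable cardiomyocytes.

    Percentages are on 0-100. ``p2n_mono`` is the diploid fraction among
    mononuclear-CM nuclei; ``mononuclear_diploid_pct`` is the product
    ``mono_pct * p2n_mono / 100`` and ``mononuclear_diploid_pct_direct`` the
    directly counted variant. ``qc_pass`` applies the minimum-cell rule
    (>=600 by default).
    """

    heart_id: str
    n_cm_counted: int
    mono_pct: float
    bi_pct: float
    tri_pct: float
    tetra_pct: float
    p2n_mono: float
    p2n_bi_nuclei: float
    mononuclear_diploid_pct: float
    mononuclear_diploid_pct_direct: float
    qc_pass: bool

    def as_dict(self) -> dict:
        return asdict(self)


def summarize_heart(cells: pd.DataFrame, calls: pd.DataFrame,
                    min_cells: int = 600,
                    heart_id: str = "heart") -> HeartSummary:
    """Compose the per-heart summary from typed viable cells and calls.

    `cells` should already be viability-filtered; CM rows are selected here
    (and any non-viable rows dropped defensively). `calls` may cover all
    nuclei; only mononuclear/binucleated-CM nuclei enter the ploidy
    fractions.
    """
    cm = cells[(cells["type"] == "CM") & cells["alive"]]
    n_cm = len(cm)
    if n_cm == 0:
        raise ValueError("no viable cardiomyocytes to summarize")
    nucleation = cm["nucleation_binned"] if "nucleation_binned" in cm else \
        cm["nucleation"].clip(upper=4)
    frac = {k: 100.0 * float((nucleation == k).sum()) / n_cm for k in (1, 2, 3, 4)}

    is2n = calls["ploidy_class"].astype(str) == "2N"
    mono_ids = set(cm.loc[nucleation == 1, "cell_id"])
    bi_ids = set(cm.loc[nucleation == 2, "cell_id"])
    mono_calls = calls[calls["cell_id"].isin(mono_ids)]
    bi_calls = calls[calls["cell_id"].isin(bi_ids)]
    p2n_mono = (100.0 * float(is2n[mono_calls.index].mean())
                if len(mono_calls) else float("nan"))
    p2n_bi = (100.0 * float(is2n[bi_calls.index].mean())
              if len(bi_calls) else float("nan"))
    mono_diploid = frac[1] * p2n_mono / 100.0 if len(mono_calls) else float("nan")
    n_mono_diploid = int(is2n[mono_calls.index].sum()) if len(mono_calls) else 0
    mono_diploid_direct = 100.0 * n_mono_diploid / n_cm

    return HeartSummary(
        heart_id=str(heart_id), n_cm_counted=n_cm,
        mono_pct=frac[1], bi_pct=frac[2], tri_pct=frac[3], tetra_pct=frac[4],
        p2n_mono=p2n_mono, p2n_bi_nuclei=p2n_bi,
        mononuclear_diploid_pct=mono_diploid,
        mononuclear_diploid_pct_direct=mono_diploid_direct,
        qc_pass=n_cm >= min_cells)


@dataclass
class GroupComparison:
    """Unpaired two-tailed Student t comparison of a per-heart metric."""

    label_a: str
    label_b: str
    metric: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    t: float
    df: float
    p: float
    welch: bool

    def as_dict(self) -> dict:
        return asdict(self)


def _metric_values(group, metric: str) -> np.ndarray:
    if isinstance(group, pd.DataFrame):
        return group[metric].to_numpy(dtype=float)
    vals = []
    for item in group:
        if isinstance(item, HeartSummary):
            vals.append(getattr(item, metric))
        elif isinstance(item, dict):
            vals.append(item[metric])
        else:
            vals.append(float(item))
    return np.asarray(vals, dtype=float)


def compare_groups(a, b, metric: str = "mono_pct", welch: bool = False,
                   label_a: str = "A", label_b: str = "B") -> GroupComparison:
    """Unpaired two-tailed t-test on a per-heart metric.

    Pooled-variance Student t by default (df = n_a + n_b - 2); Welch's
    unequal-variance form when ``welch=True``. Each group needs >=2 hearts.
    Two groups with zero pooled variance and equal means give t=0, p=1.
    """
    xa, xb = _metric_values(a, metric), _metric_values(b, metric)
    if len(xa) < 2 or len(xb) < 2:
        raise ValueError(
            f"need >=2 hearts per group, got {len(xa)} and {len(xb)}")
    res = stats.ttest_ind(xa, xb, equal_var=not welch)
    t, p, df = float(res.statistic), float(res.pvalue), float(res.df)
    if not np.isfinite(t):  # zero variance in both groups
        if np.isclose(xa.mean(), xb.mean()):
            t, p = 0.0, 1.0
        else:
            t = math.inf if xa.mean() > xb.mean() else -math.inf
            p = 0.0
    return GroupComparison(
        label_a=label_a, label_b=label_b, metric=metric,
        n_a=len(xa), n_b=len(xb),
        mean_a=float(xa.mean()), mean_b=float(xb.mean()),
        sd_a=float(xa.std(ddof=1)), sd_b=float(xb.std(ddof=1)),
        t=t, df=df, p=p, welch=welch)
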