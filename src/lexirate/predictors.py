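"""Sociodemographic predictor transforms, design matrix and diagnostics.

Five per-language predictors: population size (log-transformed),
geographical isolation (log of the distance in km to the nearest
landmass inhabited by a different culture; same-island contact is coded
0 km, so log(x+1) keeps the value finite and maps 0 -> 0), and three
4-point conflict ordinals coded 1 = most conflict .. 4 = least in the
source database.  The ordinals are reversed (v -> 5 - v) so that larger
always means more conflict, and every column is z-standardised over the
analysis sample so effect sizes are directly comparable.

Diagnostics mirror the standard pre-model checks: variance inflation
factors (all predictors are continuous after standardisation, so GVIF
reduces to plain VIF, flagged at >= 2), pairwise Pearson correlations,
and a chi-squared independence test for categorical cross-tabulations.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, SchemaError
from .phylo_pairs import SisterPair

logger = logging.getLogger(__name__)

#: transformed predictor names, in the order of the model formula
PREDICTORS = (
    "logPopulation",
    "ConflictWithinCommunities",
    "Isolation",
    "ConflictWithinCultures",
    "ConflictBetweenCultures",
)

RAW_COLUMNS = (
    "population_size",
    "distance_km",
    "conflict_within",
    "warfare_internal",
    "warfare_external",
)

PAIRING_MODES = ("pair_mean", "two_row", "signed_contrast")

VIF_FLAG_THRESHOLD = 2.0


def transform_predictors(
    raw: pd.DataFrame,
    sample: Iterable[str] | None = None,
    *,
    distance_offset_km: float = 1.0,
) -> pd.DataFrame:
    """Transform and z-standardise the five raw predictors.

    ``raw`` is indexed by language id (or carries a ``language`` column).
    Standardisation (mean 0, sd 1 with the n-1 convention) is computed
    over ``sample`` — exactly the analysis languages — after the
    transforms and before any pair-level aggregation.
    """
    if "language" in raw.columns:
        raw = raw.set_index("language")
    missing = [c for c in RAW_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"predictor table is missing column(s) {missing}")
    sample_ids = list(sample) if sample is not None else list(raw.index)
    absent = [l for l in sample_ids if l not in raw.index]
    if absent:
        raise DataError(f"sample language(s) missing from predictor table: {absent}")
    data = raw.loc[sample_ids, list(RAW_COLUMNS)].astype(float)

    if (data["population_size"] <= 0).any():
        bad = data.index[data["population_size"] <= 0].tolist()
        raise DataError(f"non-positive population size for {bad}")
    if (data["distance_km"] < 0).any():
        raise DataError("negative distance_km")
    for col in ("conflict_within", "warfare_internal", "warfare_external"):
        if not data[col].isin([1, 2, 3, 4]).all():
            bad = data.index[~data[col].isin([1, 2, 3, 4])].tolist()
            raise DataError(f"{col} outside the 1-4 ordinal scale for {bad}")

    out = pd.DataFrame(index=data.index)
    out["logPopulation"] = np.log(data["population_size"])
    out["Isolation"] = np.log(data["distance_km"] + distance_offset_km)
    # reverse so that higher = more conflict
    out["ConflictWithinCommunities"] = 5.0 - data["conflict_within"]
    out["ConflictWithinCultures"] = 5.0 - data["warfare_internal"]
    out["ConflictBetweenCultures"] = 5.0 - data["warfare_external"]

    for col in PREDICTORS:
        sd = out[col].std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise DataError(f"predictor {col} has zero variance over the sample")
        out[col] = (out[col] - out[col].mean()) / sd
    return out[list(PREDICTORS)]


def build_design(
    pairs: Sequence[SisterPair],
    pred: pd.DataFrame,
    events: pd.DataFrame | None,
    *,
    mode: str = "pair_mean",
    focal: str = "logPopulation",
) -> pd.DataFrame:
    """Assemble the per-observation design table under a pairing mode.

    ``pair_mean`` (default): one row per pair; each predictor is the mean
    of the two sisters' standardised values and the responses are the
    pair totals.  ``two_row``: one row per language with its own values
    and its own branch counts.  ``signed_contrast`` (experimental): one
    row per pair with within-pair differences, oriented so the ``focal``
    predictor difference is non-negative, responses taken from the first
    sister under that orientation.
    """
    if mode not in PAIRING_MODES:
        raise DataError(f"unknown pairing mode {mode!r}; choose from {PAIRING_MODES}")
    # events=None builds a covariate-only design (responses all zero),
    # used by the simulator before any counts exist
    ev = events.set_index("pair") if events is not None else None
    zero = pd.Series(0, index=["gains", "losses", "turnover",
                               "gains_a", "gains_b", "losses_a", "losses_b"])
    rows = []
    for pair in pairs:
        a, b = pair.language_a, pair.language_b
        for lang in (a, b):
            if lang not in pred.index:
                raise DataError(f"language {lang!r} missing from predictor table")
        e = ev.loc[pair.pair_id] if ev is not None else zero
        xa, xb = pred.loc[a, list(PREDICTORS)], pred.loc[b, list(PREDICTORS)]
        if mode == "pair_mean":
            row = dict(((xa + xb) / 2.0))
            row.update(
                pair=pair.pair_id, unit=pair.pair_id,
                gains=int(e["gains"]), losses=int(e["losses"]), turnover=int(e["turnover"]),
            )
            rows.append(row)
        elif mode == "two_row":
            for lang, x, suffix in ((a, xa, "a"), (b, xb, "b")):
                row = dict(x)
                g, l = int(e[f"gains_{suffix}"]), int(e[f"losses_{suffix}"])
                row.update(pair=pair.pair_id, unit=lang, gains=g, losses=l, turnover=g + l)
                rows.append(row)
        else:  # signed_contrast
            diff = xa - xb
            first = "a"
            if diff[focal] < 0:
                diff, first = -diff, "b"
            row = dict(diff)
            g, l = int(e[f"gains_{first}"]), int(e[f"losses_{first}"])
            row.update(pair=pair.pair_id, unit=pair.pair_id, gains=g, losses=l, turnover=g + l)
            rows.append(row)
    design = pd.DataFrame(rows)
    if design.empty:
        design = pd.DataFrame(
            columns=list(PREDICTORS) + ["pair", "unit", "gains", "losses", "turnover"]
        )
    design.attrs["pairing_mode"] = mode
    if not np.isfinite(design[list(PREDICTORS)].to_numpy(dtype=float)).all():
        raise DataError("non-finite predictor values in design table")
    return design


def gvif(design: pd.DataFrame, predictors: Sequence[str] = PREDICTORS) -> pd.Series:
    """Variance inflation factor per predictor (flagged at >= 2).

    Each predictor is regressed (with intercept) on the others; the
    factor is 1 / (1 - R^2).  Perfect collinearity reports inf.
    """
    X = design[list(predictors)].to_numpy(dtype=float)
    n, p = X.shape
    if p < 2:
        raise DataError("VIF needs at least two predictors")
    if n <= p:
        raise DataError("VIF needs more rows than predictors")
    out = {}
    for j, name in enumerate(predictors):
        y = X[:, j]
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        beta, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ beta
        tss = np.sum((y - y.mean()) ** 2)
        r2 = 1.0 - np.sum(resid**2) / tss if tss > 0 else 1.0
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    result = pd.Series(out, name="vif")
    flagged = result[result >= VIF_FLAG_THRESHOLD]
    for name, value in flagged.items():
        logger.warning("collinearity flag: VIF(%s) = %g >= %g", name, value, VIF_FLAG_THRESHOLD)
    return result


def correlation_matrix(pred: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson r with two-sided p-values (t transform of r)."""
    cols = [c for c in pred.columns if np.issubdtype(pred[c].dtype, np.number)]
    if len(pred) < 3:
        raise DataError("correlation matrix needs at least 3 rows")
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    for i, ci in enumerate(cols):
        for j, cj in enumerate(cols):
            if j <= i:
                continue
            x, y = pred[ci].to_numpy(float), pred[cj].to_numpy(float)
            if np.std(x) == 0 or np.std(y) == 0:
                warnings.warn(f"zero-variance column in correlation: {ci} vs {cj}")
                r.loc[ci, cj] = r.loc[cj, ci] = np.nan
                p.loc[ci, cj] = p.loc[cj, ci] = np.nan
                continue
            res = stats.pearsonr(x, y)
            r.loc[ci, cj] = r.loc[cj, ci] = res.statistic
            p.loc[ci, cj] = p.loc[cj, ci] = res.pvalue
    return r, p


def chisq_independence(a: Sequence, b: Sequence) -> dict:
    """Pearson chi-squared test of independence on the cross-tabulation.

    Returns ``{"statistic", "df", "p", "low_expected"}``; ``low_expected``
    flags any expected cell count below 5 (the usual reliability caveat).
    """
    a, b = pd.Series(list(a)), pd.Series(list(b))
    if len(a) != len(b):
        raise DataError("chi-squared inputs differ in length")
    table = pd.crosstab(a, b)
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise DataError("chi-squared test needs >= 2 levels in each variable")
    res = stats.chi2_contingency(table.to_numpy(), correction=False)
    low = bool((res.expected_freq < 5).any())
    if low:
        warnings.warn("chi-squared: some expected counts < 5; p-value is approximate")
    return {
        "statistic": float(res.statistic),
        "df": int(res.dof),
        "p": float(res.pvalue),
        "low_expected": low,
    }
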