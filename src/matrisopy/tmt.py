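"""Quantitative TMT stage comparison: QC, normalization, batch cleanup, and
empirical-Bayes moderated differential statistics.

The statistical core follows the standard empirical-Bayes linear-model
formulation for isobaric-label proteomics: per-protein ordinary least squares
on a design of life-stage and replicate/batch factors, residual variances
shrunk toward a prior fitted by method of moments on log variances
(scaled-F model with prior degrees of freedom d0 and prior variance s0^2),
and a moderated t-statistic

    t_g = fc_g / (s_tilde_g * sqrt(v_c)),
    s_tilde_g^2 = (d0 * s0^2 + df_g * s_g^2) / (d0 + df_g),

referred to a t distribution with d0 + df_g degrees of freedom (normal when
d0 is infinite).  Hits are proteins with BH false-discovery rate below 5% and
an absolute fold change of at least 2 (the fold-change bound inclusive).

The modelling surface is statsmodels-style: build a
:class:`DifferentialAbundanceModel` from a :class:`TMTExperiment`, call
``fit()``, and read estimates/statistics off the returned
:class:`DifferentialAbundanceResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TMTExperiment",
    "EBParameters",
    "DifferentialAbundanceModel",
    "DifferentialAbundanceResults",
    "read_intensity_table",
    "write_intensity_table",
    "qc_filter",
    "log2_transform",
    "aggregate_technical_replicates",
    "remove_batch_effects",
    "vs_normalize",
    "fit_eb_parameters",
    "trigamma_inverse",
    "moderated_ttest",
    "benjamini_hochberg",
    "call_hits",
    "stage_medians",
]

SCALES = ("raw", "log2", "normalized")
LIFE_STAGES = ("larva", "primary_polyp", "adult")


@dataclass
class TMTExperiment:
    """A reporter-intensity matrix with protein and sample metadata.

    ``matrix`` is proteins x samples.  ``proteins`` (indexed by protein id)
    carries ``unique_peptides`` and ``contaminant``; ``samples`` (indexed by
    sample id) carries ``life_stage``, ``replicate`` and ``batch``.  The
    ``scale`` tag tracks the raw -> log2 -> normalized transitions.
    """

    matrix: pd.DataFrame
    proteins: pd.DataFrame
    samples: pd.DataFrame
    scale: str = "raw"
    log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale tag {self.scale!r}")
        if not self.matrix.index.equals(self.proteins.index):
            raise ValueError("matrix rows do not match protein metadata")
        if not self.matrix.columns.equals(self.samples.index):
            raise ValueError("matrix columns do not match sample metadata")

    @property
    def n_proteins(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    def copy(self) -> "TMTExperiment":
        return TMTExperiment(self.matrix.copy(), self.proteins.copy(),
                             self.samples.copy(), self.scale, dict(self.log))


def read_intensity_table(
    matrix_path: str | Path, sample_sheet_path: str | Path
) -> TMTExperiment:
    """Read an intensity TSV (rows = proteins) plus its companion sample sheet.

    The matrix must carry a ``protein_id`` column, one column per sample named
    in the sheet, and ``unique_peptides`` / ``contaminant`` columns.  Every
    sample in the sheet must be a matrix column and vice versa.
    """
    df = pd.read_csv(matrix_path, sep="\t", dtype={"protein_id": str})
    df = df.set_index("protein_id")
    sheet = pd.read_csv(sample_sheet_path, sep="\t", dtype=str)
    sheet = sheet.set_index("sample_id")
    meta_cols = {"unique_peptides", "contaminant"}
    sample_cols = [c for c in df.columns if c not in meta_cols]
    if set(sample_cols) != set(sheet.index):
        missing = set(sheet.index) ^ set(sample_cols)
        raise ValueError(f"sample sheet / matrix column mismatch: {sorted(missing)}")
    proteins = pd.DataFrame({
        "unique_peptides": df["unique_peptides"].astype(int),
        "contaminant": df["contaminant"].astype(bool)
        if df["contaminant"].dtype == bool
        else df["contaminant"].astype(str).str.lower().isin(("true", "1", "yes")),
    })
    matrix = df[list(sheet.index)].astype(float)
    return TMTExperiment(matrix, proteins, sheet, scale="raw")


def write_intensity_table(
    exp: TMTExperiment, matrix_path: str | Path, sample_sheet_path: str | Path
) -> None:
    out = exp.matrix.copy()
    out["unique_peptides"] = exp.proteins["unique_peptides"]
    out["contaminant"] = exp.proteins["contaminant"]
    out.index.name = "protein_id"
    out.to_csv(matrix_path, sep="\t")
    sheet = exp.samples.copy()
    sheet.index.name = "sample_id"
    sheet.to_csv(sample_sheet_path, sep="\t")


# ---------------------------------------------------------------------------
# Preprocessing

def qc_filter(exp: TMTExperiment, min_unique_peptides: int = 2) -> TMTExperiment:
    """Drop contaminant-flagged proteins and those quantified with fewer than
    ``min_unique_peptides`` unique peptides (default 2)."""
    if exp.scale != "raw":
        raise ValueError("qc_filter expects a raw-scale experiment")
    contaminant = exp.proteins["contaminant"].to_numpy(bool)
    low = exp.proteins["unique_peptides"].to_numpy() < min_unique_peptides
    keep = ~(contaminant | low)
    out = TMTExperiment(exp.matrix.loc[keep], exp.proteins.loc[keep],
                        exp.samples, scale="raw", log=dict(exp.log))
    out.log["qc_removed_contaminant"] = int(contaminant.sum())
    out.log["qc_removed_low_peptides"] = int((low & ~contaminant).sum())
    return out


def log2_transform(exp: TMTExperiment) -> TMTExperiment:
    """Elementwise log2 of raw intensities; zeros become missing (recorded)."""
    if exp.scale != "raw":
        raise ValueError("log2_transform expects a raw-scale experiment")
    values = exp.matrix.to_numpy(float)
    if np.nanmin(values) < 0:
        raise ValueError("negative intensity encountered")
    n_zero = int((values == 0).sum())
    with np.errstate(divide="ignore"):
        logged = np.where(values > 0, np.log2(np.where(values > 0, values, 1.0)),
                          np.nan)
    out = TMTExperiment(
        pd.DataFrame(logged, index=exp.matrix.index, columns=exp.matrix.columns),
        exp.proteins, exp.samples, scale="log2", log=dict(exp.log))
    out.log["zeros_set_missing"] = n_zero
    return out


def aggregate_technical_replicates(
    exp: TMTExperiment, key: str = "biological_sample"
) -> TMTExperiment:
    """Average technical-replicate columns down to one column per biological
    sample (grouping key taken from the sample sheet)."""
    if key not in exp.samples.columns:
        return exp
    groups = exp.samples.groupby(key, sort=False)
    cols, meta_rows = [], []
    for name, sub in groups:
        cols.append(exp.matrix[sub.index].mean(axis=1).rename(str(name)))
        meta = sub.iloc[0].copy()
        meta.name = str(name)
        meta_rows.append(meta)
    matrix = pd.concat(cols, axis=1)
    samples = pd.DataFrame(meta_rows).drop(columns=[key], errors="ignore")
    return TMTExperiment(matrix, exp.proteins, samples, exp.scale, dict(exp.log))


def _design_matrix(
    samples: pd.DataFrame, condition: str, blocks: Sequence[str]
) -> tuple[np.ndarray, list[str]]:
    """Cell-means coding for the condition + treatment-coded block factors."""
    cond = pd.get_dummies(samples[condition], dtype=float)
    parts = [cond]
    names = [f"{condition}:{c}" for c in cond.columns]
    for b in blocks:
        if b not in samples.columns:
            continue
        if samples[b].nunique() < 2:
            continue
        dummies = pd.get_dummies(samples[b], drop_first=True, dtype=float)
        parts.append(dummies)
        names += [f"{b}:{c}" for c in dummies.columns]
    X = np.column_stack([p.to_numpy() for p in parts])
    return X, names


def remove_batch_effects(
    exp: TMTExperiment, batch: str = "batch", condition: str = "life_stage"
) -> TMTExperiment:
    """Subtract estimated batch components from a log2 matrix.

    Per protein, an OLS fit on condition (cell-means) plus treatment-coded
    batch indicators; only the batch components are removed, so the condition
    structure is preserved.  A single batch level is a no-op.
    """
    if exp.scale != "log2":
        raise ValueError("remove_batch_effects expects a log2-scale experiment")
    if exp.samples[batch].nunique() < 2:
        return exp.copy()
    X, names = _design_matrix(exp.samples, condition, [batch])
    n_cond = exp.samples[condition].nunique()
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            f"design is rank-deficient: factors {condition!r} and {batch!r} "
            "are confounded")
    batch_cols = np.arange(n_cond, X.shape[1])
    Y = exp.matrix.to_numpy(float)
    corrected = Y.copy()
    complete = ~np.isnan(Y).any(axis=1)
    if complete.any():
        beta, *_ = np.linalg.lstsq(X, Y[complete].T, rcond=None)
        corrected[complete] = (Y[complete].T - X[:, batch_cols]
                               @ beta[batch_cols]).T
    for i in np.flatnonzero(~complete):
        obs = ~np.isnan(Y[i])
        Xi = X[obs]
        if np.linalg.matrix_rank(Xi) < Xi.shape[1]:
            continue  # cannot separate batch from condition for this protein
        beta, *_ = np.linalg.lstsq(Xi, Y[i, obs], rcond=None)
        corrected[i, obs] = Y[i, obs] - X[obs][:, batch_cols] @ beta[batch_cols]
    out = TMTExperiment(
        pd.DataFrame(corrected, index=exp.matrix.index,
                     columns=exp.matrix.columns),
        exp.proteins, exp.samples, scale="log2", log=dict(exp.log))
    out.log["batch_corrected"] = True
    return out


def _median_center(values: np.ndarray) -> np.ndarray:
    med = np.nanmedian(values, axis=0)
    centered = values - med
    mad = np.nanmedian(np.abs(centered), axis=0)
    mad = np.where(mad > 0, mad, 1.0)
    target = float(np.mean(mad))
    return centered / mad * target


def _affine_arsinh(
    values: np.ndarray, max_iter: int = 50, tol: float = 1e-6,
    trim: float = 0.9,
) -> np.ndarray:
    """Per-sample affine-arsinh calibration h_s(x) = arsinh(a_s + b_s x).

    Parameters are chosen by iterative least-trimmed-squares against the
    across-sample mean profile, over the middle ``trim`` fraction of proteins;
    sample 1 anchors the scale (a=0, b set from its spread) so the trivial
    constant solution is excluded.  b_s > 0 is enforced, so each calibration
    is strictly increasing.
    """
    m, n = values.shape
    b0 = 1.0 / max(np.nanstd(values[:, 0]), 1e-12)
    params = np.zeros((n, 2))
    params[:, 1] = b0  # (a_s, b_s); sample 0 stays fixed
    keep = max(int(np.ceil(trim * m)), 2)

    def transform(p):
        return np.arcsinh(p[:, 0][None, :] + p[:, 1][None, :] * values)

    for _ in range(max_iter):
        H = transform(params)
        target = np.nanmean(H, axis=1)
        new = params.copy()
        for s in range(1, n):
            obs = ~np.isnan(values[:, s]) & ~np.isnan(target)
            x, t = values[obs, s], target[obs]

            def resid(theta, x=x, t=t):
                r = np.arcsinh(theta[0] + np.exp(theta[1]) * x) - t
                if r.size > keep:
                    idx = np.argpartition(np.abs(r), keep - 1)[:keep]
                    r = r[idx]
                return r

            theta0 = np.array([params[s, 0], np.log(params[s, 1])])
            # bound log(b) near the anchor scale so b > 0 cannot collapse
            sol = optimize.least_squares(
                resid, theta0, method="trf",
                bounds=([-np.inf, np.log(b0) - 8.0],
                        [np.inf, np.log(b0) + 8.0]))
            new[s] = [sol.x[0], np.exp(sol.x[1])]
        delta = np.max(np.abs(new - params))
        params = new
        if delta < tol:
            break
    else:
        warnings.warn("affine-arsinh calibration did not converge; "
                      "returning best iterate", RuntimeWarning)
    return transform(params)


def vs_normalize(exp: TMTExperiment, method: str = "median_center") -> TMTExperiment:
    """Variance-stabilizing sample calibration.

    ``median_center`` (on log2 data): subtract each sample's median, rescale
    to a common median absolute deviation.  ``affine_arsinh`` (on raw data):
    per-sample arsinh calibration fitted by iterative trimmed least squares.
    """
    values = exp.matrix.to_numpy(float)
    if method == "median_center":
        if exp.scale != "log2":
            raise ValueError("median_center expects a log2-scale experiment")
        normalized = _median_center(values)
    elif method == "affine_arsinh":
        if exp.scale != "raw":
            raise ValueError("affine_arsinh expects a raw-scale experiment")
        normalized = _affine_arsinh(values)
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    out = TMTExperiment(
        pd.DataFrame(normalized, index=exp.matrix.index,
                     columns=exp.matrix.columns),
        exp.proteins, exp.samples, scale="normalized", log=dict(exp.log))
    out.log["normalization"] = method
    return out


# ---------------------------------------------------------------------------
# Empirical-Bayes variance moderation

@dataclass(frozen=True)
class EBParameters:
    """Prior for the scaled-F variance model: d0 degrees of freedom, s0^2
    variance.  ``d0 = inf`` means complete pooling; ``d0 = 0`` disables
    moderation (ordinary t) and only arises by explicit request."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if self.d0 < 0:
            raise ValueError("d0 must be nonnegative")
        if not self.s0_sq > 0:
            raise ValueError("s0_sq must be positive")


def trigamma_inverse(y: float, max_iter: int = 50, tol: float = 1e-10) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration.

    Monotone-decreasing trigamma makes the iteration globally convergent from
    the standard starting point x = 0.5 + 1/y.
    """
    if y <= 0:
        raise ValueError("trigamma_inverse requires y > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < tol * x:
            break
    return float(x)


def fit_eb_parameters(
    residual_variances: Sequence[tuple[float, float]]
) -> EBParameters:
    """Method-of-moments fit of (d0, s0^2) on log residual variances.

    Under the scaled-F model s_g^2 ~ s0^2 * F(df_g, d0), the mean and variance
    of log s_g^2 are digamma/trigamma expressions in df_g and d0; matching the
    observed moments gives a trigamma equation for d0 solved by Newton.  When
    the observed dispersion of log variances does not exceed what the sampling
    distribution alone explains, d0 is infinite (all variances shrunk to s0^2).
    """
    usable = [(s2, df) for s2, df in residual_variances if df >= 1 and s2 > 0]
    if len(usable) < 10:
        raise ValueError(
            f"need >= 10 proteins with positive variance and df >= 1, "
            f"got {len(usable)}")
    s2 = np.array([u[0] for u in usable])
    df = np.array([u[1] for u in usable])
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1) - np.mean(special.polygamma(1, df / 2.0)))
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s0_sq = float(np.exp(
            emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        # zero excess dispersion: complete pooling to the geometric mean of
        # the observed variances (the common value when they are identical)
        d0 = np.inf
        s0_sq = float(np.exp(np.mean(z)))
    return EBParameters(d0=d0, s0_sq=s0_sq)


# ---------------------------------------------------------------------------
# Multiple testing and hit calling

def benjamini_hochberg(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p, float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_hits(
    results: pd.DataFrame, fc_threshold: float = 2.0,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Annotate hits: fdr strictly below threshold AND |log2 fc| at least
    log2(fc_threshold) (the fold-change bound is inclusive)."""
    if fc_threshold <= 0 or fdr_threshold <= 0:
        raise ValueError("thresholds must be positive")
    out = results.copy()
    out["hit"] = ((out["fdr"] < fdr_threshold)
                  & (np.abs(out["log2_fc"]) >= np.log2(fc_threshold)))
    out["direction"] = np.where(
        out["hit"], np.where(out["log2_fc"] > 0, "up", "down"), "")
    return out


def stage_medians(
    exp: TMTExperiment, stages: Optional[Sequence[str]] = None,
    condition: str = "life_stage",
) -> pd.DataFrame:
    """Per protein and life stage, the median across that stage's samples."""
    if exp.scale != "normalized":
        raise ValueError("stage_medians expects a normalized experiment")
    if stages is None:
        stages = list(dict.fromkeys(exp.samples[condition]))
    cols = {}
    for stage in stages:
        ids = exp.samples.index[exp.samples[condition] == stage]
        if len(ids) == 0:
            raise ValueError(f"stage {stage!r} has no samples")
        cols[stage] = exp.matrix[ids].median(axis=1)
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# The Model / Results pair

class DifferentialAbundanceModel:
    """Per-protein linear model for stage contrasts on a normalized matrix.

    Parameters
    ----------
    exp:
        A ``scale == "normalized"`` experiment.
    condition:
        Sample-sheet column holding the contrasted factor (default life_stage).
    blocks:
        Extra factors absorbed into the design (replicate and/or batch).
    """

    def __init__(self, exp: TMTExperiment, condition: str = "life_stage",
                 blocks: Sequence[str] = ("replicate",)) -> None:
        if exp.scale != "normalized":
            raise ValueError("model expects a normalized experiment")
        self.exp = exp
        self.condition = condition
        self.blocks = tuple(blocks)
        self.X, self.coef_names = _design_matrix(exp.samples, condition, blocks)
        self.levels = list(pd.get_dummies(exp.samples[condition]).columns)

    def _contrast_vector(self, contrast: tuple[str, str]) -> np.ndarray:
        a, b = contrast
        if a not in self.levels or b not in self.levels:
            raise KeyError(f"unknown condition level in contrast {contrast}")
        c = np.zeros(self.X.shape[1])
        c[self.levels.index(a)] = 1.0
        c[self.levels.index(b)] = -1.0
        return c

    def fit(
        self,
        contrasts: Optional[Sequence[tuple[str, str]]] = None,
        eb: EBParameters | str = "fit",
        min_obs_per_group: int = 2,
    ) -> "DifferentialAbundanceResults":
        """OLS per protein, empirical-Bayes shrinkage, moderated t per contrast.

        ``eb="fit"`` estimates the variance prior from the residual variances;
        an :class:`EBParameters` instance fixes it.  Proteins with fewer than
        ``min_obs_per_group`` observations in a contrasted group are dropped
        from that contrast (reported in the results).
        """
        exp = self.exp
        if contrasts is None:
            lv = [s for s in LIFE_STAGES if s in self.levels] or self.levels
            contrasts = [(lv[j], lv[i]) for i in range(len(lv))
                         for j in range(i + 1, len(lv))]
        Y = exp.matrix.to_numpy(float)
        m, n = Y.shape
        X = self.X
        k = X.shape[1]
        rank = np.linalg.matrix_rank(X)
        if rank < k:
            raise ValueError("rank-deficient design matrix")

        beta = np.full((m, k), np.nan)
        s2 = np.full(m, np.nan)
        dfree = np.zeros(m)
        xtx_inv = np.linalg.inv(X.T @ X)
        complete = ~np.isnan(Y).any(axis=1)
        if complete.any():
            Yc = Y[complete]
            b = xtx_inv @ X.T @ Yc.T
            resid = Yc.T - X @ b
            beta[complete] = b.T
            dfree[complete] = n - rank
            s2[complete] = (resid ** 2).sum(axis=0) / max(n - rank, 1)
        vc_default = {}
        per_protein_xtxinv: dict[int, np.ndarray] = {}
        for i in np.flatnonzero(~complete):
            obs = ~np.isnan(Y[i])
            Xi = X[obs]
            ri = np.linalg.matrix_rank(Xi)
            if ri < k or obs.sum() <= ri:
                continue
            xtxi = np.linalg.inv(Xi.T @ Xi)
            bi = xtxi @ Xi.T @ Y[i, obs]
            res = Y[i, obs] - Xi @ bi
            beta[i] = bi
            dfree[i] = obs.sum() - ri
            s2[i] = float(res @ res) / dfree[i]
            per_protein_xtxinv[i] = xtxi

        fitted = (dfree > 0) & ~np.isnan(s2)
        if eb == "fit":
            eb_params = fit_eb_parameters(
                list(zip(s2[fitted], dfree[fitted])))
        elif isinstance(eb, EBParameters):
            eb_params = eb
        else:
            raise ValueError("eb must be 'fit' or an EBParameters instance")

        d0, s0 = eb_params.d0, eb_params.s0_sq
        has_fit = ~np.isnan(beta).any(axis=1)
        if not np.isinf(d0):
            if np.any(has_fit & (dfree == 0)):
                raise ValueError(
                    "zero residual degrees of freedom with finite d0")
            post_var = (d0 * s0 + dfree * s2) / np.where(
                d0 + dfree > 0, d0 + dfree, np.nan)
            post_df = d0 + dfree
        else:
            post_var = np.full(m, s0)
            post_df = np.full(m, np.inf)

        tables = {}
        for contrast in contrasts:
            c = self._contrast_vector(contrast)
            vc = float(c @ xtx_inv @ c)
            fc = beta @ c
            v = np.full(m, vc)
            for i, xtxi in per_protein_xtxinv.items():
                v[i] = float(c @ xtxi @ c)
            # group-size gate for this contrast
            ok = has_fit & (np.isinf(d0) | (dfree > 0))
            for level in contrast:
                in_group = (exp.samples[self.condition] == level).to_numpy()
                n_obs = (~np.isnan(Y[:, in_group])).sum(axis=1)
                ok &= n_obs >= min_obs_per_group
            se = np.sqrt(post_var * v)
            with np.errstate(divide="ignore", invalid="ignore"):
                t = np.where(se > 0, fc / se, 0.0)
            t = np.where(np.isnan(fc), np.nan, t)
            if np.isinf(d0):
                p = 2.0 * stats.norm.sf(np.abs(t))
            else:
                p = 2.0 * stats.t.sf(np.abs(t), post_df)
            p = np.clip(p, np.nextafter(0, 1), 1.0)
            frame = pd.DataFrame({
                "protein_id": exp.matrix.index,
                "log2_fc": fc,
                "moderated_t": t,
                "p": p,
                "df_residual": dfree,
                "s2": s2,
                "posterior_s2": post_var,
            }).set_index("protein_id")
            frame = frame[ok]
            frame["fdr"] = benjamini_hochberg(frame["p"].to_numpy())
            tables[contrast] = frame
        return DifferentialAbundanceResults(
            model=self, eb=eb_params, tables=tables,
            n_dropped={c: int(m - len(t)) for c, t in tables.items()})


@dataclass
class DifferentialAbundanceResults:
    """Fitted contrasts: one table per stage pair, plus the variance prior."""

    model: DifferentialAbundanceModel
    eb: EBParameters
    tables: dict[tuple[str, str], pd.DataFrame]
    n_dropped: dict[tuple[str, str], int] = field(default_factory=dict)

    def frame(self, contrast: tuple[str, str]) -> pd.DataFrame:
        return self.tables[contrast]

    def call_hits(self, fc_threshold: float = 2.0,
                  fdr_threshold: float = 0.05) -> "DifferentialAbundanceResults":
        tables = {c: call_hits(t, fc_threshold, fdr_threshold)
                  for c, t in self.tables.items()}
        return replace(self, tables=tables)

    def hit_counts(self) -> dict[tuple[str, str], dict[str, int]]:
        out = {}
        for c, t in self.tables.items():
            if "hit" not in t.columns:
                raise ValueError("call_hits() has not been applied")
            out[c] = {
                "up": int(((t["hit"]) & (t["log2_fc"] > 0)).sum()),
                "down": int(((t["hit"]) & (t["log2_fc"] < 0)).sum()),
                "total": int(t["hit"].sum()),
            }
        return out

    def summary(self) -> str:
        lines = [
            "Differential abundance (empirical-Bayes moderated t)",
            f"  proteins: {self.model.exp.n_proteins}   "
            f"samples: {self.model.exp.n_samples}",
            f"  prior: d0 = {self.eb.d0:.4g}, s0^2 = {self.eb.s0_sq:.4g}",
        ]
        for c, t in self.tables.items():
            line = f"  {c[0]} vs {c[1]}: {len(t)} proteins tested"
            if "hit" in t.columns:
                up = int((t["hit"] & (t["log2_fc"] > 0)).sum())
                down = int((t["hit"] & (t["log2_fc"] < 0)).sum())
                line += f", hits: {up} up / {down} down"
            lines.append(line)
        return "\n".join(lines)

    def write(self, outdir: str | Path) -> list[Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = []
        for (a, b), t in self.tables.items():
            path = outdir / f"differential_{a}_vs_{b}.tsv"
            t.to_csv(path, sep="\t")
            paths.append(path)
        return paths


def moderated_ttest(
    exp: TMTExperiment,
    contrast: tuple[str, str],
    condition: str = "life_stage",
    blocks: Sequence[str] = ("replicate",),
    eb: EBParameters | str = "fit",
) -> pd.DataFrame:
    """Functional wrapper: fit one contrast, return its results table."""
    model = DifferentialAbundanceModel(exp, condition=condition, blocks=blocks)
    return model.fit(contrasts=[contrast], eb=eb).frame(contrast)
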