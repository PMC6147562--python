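"""Phenotype reduction: mixed-model LS means, normality screen, correlations, PCA.

Raw multi-replicate observations are reduced to one least-squares (marginal)
mean per line x treatment x trait from a linear mixed model with line,
treatment and their interaction as fixed effects and a treatment-by-tray
intercept nested within replicate as the single random term. Traits whose
residuals fail a Shapiro–Wilk normality check are log-transformed and
refitted. The LS means feed the association scan, the Bonferroni-corrected
trait-trait correlation table, and a trait-space PCA with one row per
line x treatment.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.formula.api as smf

from ._util import UserInputError, logger

__all__ = [
    "TraitMatrix",
    "TraitModelFit",
    "fit_trait_model",
    "check_normality_and_transform",
    "ls_means",
    "trait_matrix",
    "trait_correlations",
    "trait_pca",
]

REQUIRED_COLUMNS = ("line", "treatment", "replicate", "tray")


@dataclasses.dataclass
class TraitMatrix:
    """LS-mean value per (line, treatment, trait) plus transform tags.

    ``values`` is long-format with columns line, treatment, trait, value;
    missing cells are represented by NaN values and flagged. The per-treatment
    observed trait range (max - min of the LS means across lines) feeds the
    relative effect-size computation verbatim.
    """

    values: pd.DataFrame
    transforms: dict[str, str] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        need = {"line", "treatment", "trait", "value"}
        if not need.issubset(self.values.columns):
            raise UserInputError(f"trait matrix needs columns {sorted(need)}")

    @property
    def traits(self) -> list[str]:
        return list(pd.unique(self.values["trait"]))

    @property
    def treatments(self) -> list[str]:
        return list(pd.unique(self.values["treatment"]))

    def vector(self, trait: str, treatment: str) -> pd.Series:
        sub = self.values[
            (self.values["trait"] == trait) & (self.values["treatment"] == treatment)
        ]
        return sub.set_index("line")["value"].dropna()

    def range(self, trait: str, treatment: str) -> float:
        v = self.vector(trait, treatment)
        if v.empty:
            return np.nan
        return float(v.max() - v.min())

    def wide(self) -> pd.DataFrame:
        """Lines x (trait, treatment) LS-mean table."""
        return self.values.pivot_table(
            index="line", columns=["trait", "treatment"], values="value", dropna=False
        )


@dataclasses.dataclass
class TraitModelFit:
    """A fitted per-trait model: REML mixed model, or OLS after a downgrade."""

    trait: str
    result: object            # statsmodels results instance
    data: pd.DataFrame        # rows actually fitted (response column 'y')
    random_dropped: bool      # True when the tray term was dropped
    converged: bool
    transform: str = "identity"

    @property
    def residuals(self) -> np.ndarray:
        try:
            return np.asarray(self.result.resid)
        except Exception:
            # singular random-effect covariance: fall back to marginal residuals
            return np.asarray(self.result.model.endog) - np.asarray(
                self.result.predict(exog=self.data)
            )

    def random_variance(self) -> float:
        """Estimated tray-within-replicate variance (0 after a downgrade)."""
        if self.random_dropped:
            return 0.0
        cov = np.asarray(self.result.cov_re)
        return float(cov[0, 0]) if cov.size else 0.0

    def residual_variance(self) -> float:
        if self.random_dropped:
            return float(self.result.mse_resid)
        return float(self.result.scale)


def _prepare(raw: pd.DataFrame, trait: str, log: bool) -> pd.DataFrame:
    for c in REQUIRED_COLUMNS:
        if c not in raw.columns:
            raise UserInputError(f"phenotype table lacks column {c!r}")
    if trait not in raw.columns:
        raise UserInputError(f"trait column {trait!r} not in phenotype table")
    df = raw[list(REQUIRED_COLUMNS) + [trait]].copy()
    df = df.rename(columns={trait: "y"}).dropna(subset=["y"])
    if df["line"].nunique() < 2 or df["treatment"].nunique() != 2:
        raise UserInputError("need >= 2 lines and exactly two treatments")
    if log:
        if (df["y"] <= 0).any():
            raise UserInputError(f"log transform of {trait!r} needs positive values")
        df["y"] = np.log(df["y"])
    # one random grouping factor: treatment-by-tray nested within replicate
    df["tray_group"] = (
        df["replicate"].astype(str) + ":" + df["treatment"].astype(str) + ":" + df["tray"].astype(str)
    )
    df["line"] = df["line"].astype(str)
    df["treatment"] = df["treatment"].astype(str)
    return df


def fit_trait_model(
    raw: pd.DataFrame, trait: str, log: bool = False
) -> TraitModelFit:
    """REML linear mixed model for one trait.

    Fixed effects: line, treatment and their interaction. Random effect: a
    single intercept per treatment-by-tray cell nested within replicate.
    A singular or non-converging random-effect fit is downgraded to OLS on
    the same fixed effects with a logged warning.
    """
    df = _prepare(raw, trait, log)
    formula = "y ~ C(line) * C(treatment)"
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(formula, data=df, groups=df["tray_group"])
            result = model.fit(reml=True)
        if not np.isfinite(np.asarray(result.fe_params)).all() or not (
            result.scale > 0
        ):
            raise RuntimeError("singular REML fit")
        fit = TraitModelFit(
            trait, result, df, random_dropped=False, converged=bool(result.converged)
        )
        if not fit.converged:
            logger.info(
                "fit_trait_model(%s): REML optimizer stopped before the gradient "
                "tolerance; estimates retained", trait,
            )
    except Exception as exc:
        logger.warning("fit_trait_model(%s): random term dropped (%s)", trait, exc)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = smf.ols(formula, data=df).fit()
        fit = TraitModelFit(trait, result, df, random_dropped=True, converged=True)
    fit.transform = "log" if log else "identity"
    return fit


def check_normality_and_transform(
    fit: TraitModelFit, raw: pd.DataFrame, trait: str, alpha: float = 0.05
) -> TraitModelFit:
    """Shapiro–Wilk residual screen; refit on log values when rejected.

    Rejection with non-positive trait values keeps the identity scale with a
    warning (the log transform is undefined there); constant residuals make
    the test inapplicable and also keep identity.
    """
    resid = fit.residuals
    if len(resid) < 3 or np.ptp(resid) == 0:
        logger.warning("normality check for %s inapplicable; keeping identity", trait)
        return fit
    sample = resid if len(resid) <= 5000 else resid[:: max(1, len(resid) // 5000)][:5000]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, p = scipy.stats.shapiro(sample)
    if p >= alpha:
        return fit
    if (raw[trait].dropna() <= 0).any():
        logger.warning(
            "residuals of %s non-normal (Shapiro P=%.3g) but values not positive; "
            "keeping identity scale",
            trait, p,
        )
        return fit
    logger.info("residuals of %s non-normal (Shapiro P=%.3g); refitting on log scale", trait, p)
    return fit_trait_model(raw, trait, log=True)


def ls_means(fit: TraitModelFit) -> pd.DataFrame:
    """Least-squares (marginal) mean per line x treatment.

    The estimate is the fixed-effects prediction for each line x treatment
    cell, averaging over the random tray structure; on balanced data this
    equals the arithmetic cell mean. Cells with no observations are missing
    and flagged.
    """
    df = fit.data
    lines = sorted(df["line"].unique())
    treatments = sorted(df["treatment"].unique())
    grid = pd.DataFrame(
        [(l, t) for l in lines for t in treatments], columns=["line", "treatment"]
    )
    observed = set(map(tuple, df[["line", "treatment"]].drop_duplicates().to_numpy()))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pred = np.asarray(fit.result.predict(exog=grid))
    grid["value"] = pred
    grid["missing"] = [tuple(r) not in observed for r in grid[["line", "treatment"]].to_numpy()]
    grid.loc[grid["missing"], "value"] = np.nan
    n_missing = int(grid["missing"].sum())
    if n_missing:
        logger.warning("ls_means(%s): %d line x treatment cells unobserved", fit.trait, n_missing)
    grid["trait"] = fit.trait
    return grid[["line", "treatment", "trait", "value", "missing"]]


def trait_matrix(
    raw: pd.DataFrame,
    traits: Sequence[str] | None = None,
    engine: str = "reml",
    normality_alpha: float = 0.05,
) -> TraitMatrix:
    """Reduce a raw phenotype table to a :class:`TraitMatrix` of LS means.

    ``engine='reml'`` fits the mixed model per trait (with the normality
    screen); ``engine='cell_mean'`` uses arithmetic line x treatment means,
    which coincide with the LS means on balanced designs and skip the model
    fit for large simulation studies.
    """
    if traits is None:
        traits = [c for c in raw.columns if c not in REQUIRED_COLUMNS]
    if not traits:
        raise UserInputError("no trait columns found")
    frames = []
    transforms: dict[str, str] = {}
    if engine == "cell_mean":
        for tr in traits:
            g = (
                raw.groupby(["line", "treatment"], sort=True)[tr]
                .mean()
                .rename("value")
                .reset_index()
            )
            g["trait"] = tr
            g["missing"] = g["value"].isna()
            g["line"] = g["line"].astype(str)
            frames.append(g[["line", "treatment", "trait", "value", "missing"]])
            transforms[tr] = "identity"
    elif engine == "reml":
        for tr in traits:
            fit = fit_trait_model(raw, tr)
            fit = check_normality_and_transform(fit, raw, tr, alpha=normality_alpha)
            frames.append(ls_means(fit))
            transforms[tr] = fit.transform
    else:
        raise UserInputError(f"unknown engine {engine!r}")
    return TraitMatrix(values=pd.concat(frames, ignore_index=True), transforms=transforms)


def trait_correlations(tm: TraitMatrix, alpha: float = 0.05) -> pd.DataFrame:
    """Pearson correlations over every trait x treatment column pair.

    Pairs are formed within and across treatments over pairwise-complete LS
    means; the Bonferroni level is alpha divided by the number of pairs
    actually tested. Pairs with < 3 complete observations yield missing
    entries and do not count toward the correction.
    """
    wide = tm.wide()
    cols = list(wide.columns)
    rows = []
    for a in range(len(cols)):
        for b in range(a + 1, len(cols)):
            x = wide[cols[a]]
            y = wide[cols[b]]
            ok = x.notna() & y.notna()
            n = int(ok.sum())
            if n < 3:
                r = p = np.nan
            else:
                r, p = scipy.stats.pearsonr(x[ok], y[ok])
            rows.append(
                {
                    "trait_a": cols[a][0],
                    "treatment_a": cols[a][1],
                    "trait_b": cols[b][0],
                    "treatment_b": cols[b][1],
                    "n": n,
                    "r": r,
                    "p_value": p,
                }
            )
    out = pd.DataFrame(rows)
    n_tested = int(out["p_value"].notna().sum())
    cutoff = alpha / n_tested if n_tested else np.nan
    out["bonferroni_alpha"] = cutoff
    out["significant"] = out["p_value"] <= cutoff
    return out


@dataclasses.dataclass
class TraitPCA:
    scores: pd.DataFrame             # index (line, treatment), columns PC1..
    loadings: pd.DataFrame           # traits x components
    variance_fractions: np.ndarray   # sums to 1 over all components


def trait_pca(tm: TraitMatrix) -> TraitPCA:
    """PCA of standardized LS means with one row per line x treatment.

    Each genotype appears twice (once per treatment), so treatment separation
    shows up directly in the score space. Constant traits are dropped with a
    log entry; variance fractions are over all retained components and sum
    to 1.
    """
    mat = tm.values.pivot_table(
        index=["line", "treatment"], columns="trait", values="value"
    ).dropna(axis=0, how="any")
    if mat.shape[0] < 3:
        raise UserInputError("trait PCA needs >= 3 complete line x treatment rows")
    sd = mat.std(axis=0, ddof=1)
    constant = sd[sd == 0].index.tolist()
    if constant:
        logger.info("trait_pca: dropped constant traits %s", constant)
        mat = mat.drop(columns=constant)
        sd = sd.drop(constant)
    Z = (mat - mat.mean(axis=0)) / sd
    U, s, Vt = np.linalg.svd(Z.to_numpy(), full_matrices=False)
    var = s**2
    fracs = var / var.sum()
    k = len(s)
    # sign convention: largest-|loading| entry positive
    for j in range(k):
        i = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i] < 0:
            Vt[j] = -Vt[j]
            U[:, j] = -U[:, j]
    cols = [f"PC{i + 1}" for i in range(k)]
    scores = pd.DataFrame(U * s, index=mat.index, columns=cols)
    loadings = pd.DataFrame(Vt.T, index=mat.columns, columns=cols)
    return TraitPCA(scores=scores, loadings=loadings, variance_fractions=fracs)
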