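"""Per-gene mixed-model inference of differential fitness.

For each gene and each plant habitat, gene fitness is regressed on the
sample design::

    Fitness ~ Sample_type + Auxiliary_community + Harvest_day + (1 | flat)

with Sample_type contrasting the habitat against soil, the two covariates
as fixed effects, and a random intercept per growth flat.  The Sample_type
coefficient is the log2 fold change.  P-values come from a likelihood-ratio
test of the full versus the Sample_type-free model (both fit by maximum
likelihood); when the estimated flat variance collapses to zero the model
degrades to ordinary least squares and the coefficient t-test.

Genes whose residuals reject normality (Shapiro-Wilk) in any contrast are
omitted from the analysis.  Within each contrast, Benjamini-Hochberg FDR
control is applied over the retained genes, and genes are classified:
``association`` (mutants depleted in planta: q < 0.05 and log2FC < -1),
``negative_association`` (q < 0.05 and log2FC > 1), otherwise
``indifferent``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .design import PLANT_HABITATS
from .fitness_scores import GeneFitnessTable

__all__ = [
    "GeneModelFit",
    "DifferentialResults",
    "fit_gene_model",
    "normality_gate",
    "classify_effects",
    "run_contrasts",
]

CATEGORIES = ("association", "negative_association", "indifferent", "omitted_nonnormal")


class GeneSkipped(ValueError):
    """Raised when a gene cannot be fitted for a contrast."""


@dataclass
class GeneModelFit:
    """One gene x contrast regression fit."""

    gene: str
    contrast: str
    log2fc: float
    p_value: float
    residuals: np.ndarray
    flat_variance: float
    method: str  # "mixed", "ols", or "degenerate"
    n_samples: int
    dropped_covariates: tuple = ()


def _design_matrix(design: pd.DataFrame, contrast: str) -> tuple[pd.DataFrame, list]:
    X = pd.DataFrame(
        {
            "const": 1.0,
            "sample_type": (design["habitat"] == contrast).astype(float),
            "auxiliary_community": design["auxiliary_community"].astype(float),
            "harvest_day": (design["harvest_day"] == 2).astype(float),
        },
        index=design.index,
    )
    dropped = [
        c
        for c in ("auxiliary_community", "harvest_day")
        if X[c].nunique() == 1
    ]
    return X.drop(columns=dropped), dropped


def _fit_mixed(y: np.ndarray, X: np.ndarray, groups: np.ndarray):
    """ML MixedLM fit; Powell first (fast, robust on tiny data), falling
    back to the default optimizer before giving up."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, X, groups=groups)
        try:
            return model.fit(reml=False, method="powell")
        except (np.linalg.LinAlgError, ValueError):
            return sm.MixedLM(y, X, groups=groups).fit(reml=False)


def fit_gene_model(
    fitness_row: pd.Series,
    design: pd.DataFrame,
    contrast: str,
    variance_tol: float = 1e-8,
) -> GeneModelFit:
    """Fit the mixed model for one gene and one habitat-vs-soil contrast.

    Returns the Sample_type coefficient (log2FC), its p-value, the model
    residuals and the estimated flat variance.  Raises :class:`GeneSkipped`
    when there are fewer than two usable samples per group (or fewer than
    four overall), or when the model cannot be fit.
    """
    if contrast not in PLANT_HABITATS:
        raise ValueError(f"unknown contrast habitat {contrast!r}")
    sub = design[design["habitat"].isin((contrast, "soil"))].copy()
    sub = sub[sub["sample_id"].isin(fitness_row.dropna().index)]
    y = fitness_row.loc[sub["sample_id"]].to_numpy(dtype=float)
    n_con = int((sub["habitat"] == contrast).sum())
    n_soil = int((sub["habitat"] == "soil").sum())
    if len(sub) < 4 or n_con < 2 or n_soil < 2:
        raise GeneSkipped(
            f"{fitness_row.name}/{contrast}: {n_con} contrast and {n_soil} soil samples"
        )
    X, dropped = _design_matrix(sub, contrast)
    gene = str(fitness_row.name)

    if np.ptp(y) < 1e-12:
        return GeneModelFit(
            gene=gene, contrast=contrast, log2fc=0.0, p_value=1.0,
            residuals=np.zeros(len(y)), flat_variance=0.0,
            method="degenerate", n_samples=len(y), dropped_covariates=tuple(dropped),
        )

    groups = sub["flat"].to_numpy()
    use_mixed = len(np.unique(groups)) >= 2
    if use_mixed:
        try:
            full = _fit_mixed(y, X.to_numpy(), groups)
            flat_var = float(np.asarray(full.cov_re)[0, 0])
        except (np.linalg.LinAlgError, ValueError) as exc:
            raise GeneSkipped(f"{gene}/{contrast}: mixed model failed ({exc})") from exc
        if flat_var > variance_tol:
            X_red = X.drop(columns="sample_type")
            try:
                reduced = _fit_mixed(y, X_red.to_numpy(), groups)
            except (np.linalg.LinAlgError, ValueError) as exc:
                raise GeneSkipped(f"{gene}/{contrast}: reduced model failed ({exc})") from exc
            lr = max(0.0, 2.0 * (full.llf - reduced.llf))
            p = float(stats.chi2.sf(lr, df=1))
            idx = list(X.columns).index("sample_type")
            return GeneModelFit(
                gene=gene, contrast=contrast,
                log2fc=float(full.fe_params[idx]), p_value=p,
                residuals=np.asarray(full.resid), flat_variance=flat_var,
                method="mixed", n_samples=len(y), dropped_covariates=tuple(dropped),
            )
    # flat variance at (or below) the boundary: ordinary least squares
    ols = sm.OLS(y, X).fit()
    return GeneModelFit(
        gene=gene, contrast=contrast,
        log2fc=float(ols.params["sample_type"]),
        p_value=float(ols.pvalues["sample_type"]),
        residuals=np.asarray(ols.resid), flat_variance=0.0,
        method="ols", n_samples=len(y), dropped_covariates=tuple(dropped),
    )


def normality_gate(
    fits_by_gene: dict,
    alpha: float = 0.05,
) -> tuple[set, pd.DataFrame]:
    """Shapiro-Wilk residual-normality gate.

    ``fits_by_gene`` maps gene -> list of :class:`GeneModelFit` across
    contrasts.  A gene is omitted when the test rejects (p < alpha) in any
    contrast.  Fits with fewer than three residuals are inapplicable and
    treated as passing (with a warning).  Returns the retained gene set and
    a long frame of per-fit normality p-values.
    """
    retained = set()
    rows = []
    for gene, fits in fits_by_gene.items():
        ok = True
        for f in fits:
            resid = np.asarray(f.residuals)
            if len(resid) < 3:
                warnings.warn(
                    f"{gene}/{f.contrast}: <3 residuals, normality gate inapplicable"
                )
                p = np.nan
            elif np.ptp(resid) < 1e-12:
                p = 1.0  # constant residuals: nothing to reject
            else:
                p = float(stats.shapiro(resid).pvalue)
                if p < alpha:
                    ok = False
            rows.append({"gene": gene, "contrast": f.contrast, "normality_p": p})
        if ok:
            retained.add(gene)
    return retained, pd.DataFrame(rows)


def classify_effects(
    fits: list,
    retained: set,
    normality: pd.DataFrame,
    q_threshold: float = 0.05,
    lfc_threshold: float = 1.0,
) -> pd.DataFrame:
    """BH-adjust per contrast over retained genes and classify effects."""
    table = pd.DataFrame(
        {
            "gene": [f.gene for f in fits],
            "contrast": [f.contrast for f in fits],
            "log2fc": [f.log2fc for f in fits],
            "p_value": [f.p_value for f in fits],
            "flat_variance": [f.flat_variance for f in fits],
            "method": [f.method for f in fits],
        }
    )
    table = table.merge(normality, on=["gene", "contrast"], how="left")
    table["q_value"] = np.nan
    table["category"] = "omitted_nonnormal"
    is_retained = table["gene"].isin(retained)
    for contrast in table["contrast"].unique():
        sel = table.index[(table["contrast"] == contrast) & is_retained]
        if len(sel) == 0:
            continue
        q = multipletests(table.loc[sel, "p_value"], method="fdr_bh")[1]
        table.loc[sel, "q_value"] = q
    sig = is_retained & (table["q_value"] < q_threshold)
    table.loc[is_retained, "category"] = "indifferent"
    table.loc[sig & (table["log2fc"] < -lfc_threshold), "category"] = "association"
    table.loc[sig & (table["log2fc"] > lfc_threshold), "category"] = "negative_association"
    return table


@dataclass
class DifferentialResults:
    """Long-format per-gene, per-contrast test results plus bookkeeping."""

    table: pd.DataFrame
    retained: set
    omitted: set
    skipped: dict = field(default_factory=dict)

    def contrast(self, habitat: str) -> pd.DataFrame:
        return self.table[self.table["contrast"] == habitat].set_index("gene")

    def summary(self) -> dict:
        calls: dict = {}
        for (contrast, category), n in (
            self.table.groupby(["contrast", "category"]).size().items()
        ):
            calls.setdefault(contrast, {})[category] = int(n)
        return {
            "genes_tested": int(self.table["gene"].nunique()),
            "genes_omitted_nonnormal": len(self.omitted),
            "genes_skipped": len(self.skipped),
            "calls": calls,
        }


def run_contrasts(
    gft: GeneFitnessTable,
    design: pd.DataFrame,
    contrasts: tuple = PLANT_HABITATS,
    alpha_normality: float = 0.05,
    q_threshold: float = 0.05,
    lfc_threshold: float = 1.0,
) -> DifferentialResults:
    """Fit every gene against every contrast, gate, adjust, and classify."""
    fits_by_gene: dict = {}
    skipped: dict = {}
    for gene, row in gft.scores.iterrows():
        fits = []
        for contrast in contrasts:
            try:
                fits.append(fit_gene_model(row, design, contrast))
            except GeneSkipped as exc:
                skipped.setdefault(gene, []).append(str(exc))
        if fits:
            fits_by_gene[gene] = fits
    retained, normality = normality_gate(fits_by_gene, alpha=alpha_normality)
    all_fits = [f for fits in fits_by_gene.values() for f in fits]
    table = classify_effects(
        all_fits, retained, normality, q_threshold=q_threshold, lfc_threshold=lfc_threshold
    )
    table["n_barcodes"] = gft.n_barcodes.reindex(table["gene"]).to_numpy()
    omitted = set(fits_by_gene) - retained
    return DifferentialResults(table=table, retained=retained, omitted=omitted, skipped=skipped)
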