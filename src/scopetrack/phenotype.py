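"""Morphology and phenotype reduction: fineness ratio, mass correction, PCA.

Metabolic rates scale allometrically with body mass, so among-individual
comparisons use residuals from an ordinary least-squares regression of
log10(trait) on log10(mass).  The seven secondary metabolic traits are
reduced by a principal component analysis of their correlation matrix
(centred, unit variance); the first three axes (MET1-MET3) serve as
composite metabolic covariates downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .respirometry import MetabolicTraits

logger = logging.getLogger(__name__)

#: traits that receive the log10-log10 mass correction; recovery rate and
#: metabolic variability are used raw (no mass correction)
MASS_CORRECTED = (
    "smr",
    "mmr",
    "ams",
    "avg_mo2",
    "routine_mo2",
    "spont_min",
    "spont_max",
    "spont_ams",
)
NOT_MASS_CORRECTED = ("recovery_rate", "metabolic_variability")


def fineness_ratio(fork_length: float, body_depth: float) -> float:
    """Body slenderness: fork length divided by maximal body depth.

    Dimensionless; hydrodynamically efficient fish fall roughly in 4.5-8.
    """
    if fork_length <= 0 or body_depth <= 0:
        raise ValueError("fork_length and body_depth must be positive")
    return fork_length / body_depth


@dataclass
class MassCorrection:
    """OLS fit of log10(trait) on log10(mass) and its per-fish residuals."""

    slope: float
    intercept: float
    residuals: np.ndarray  # log10-scale, same order as input


def mass_correct(trait: np.ndarray, mass: np.ndarray) -> MassCorrection:
    """Residuals of log10(trait) regressed on log10(body mass).

    Residuals are mass-independent metabolic scores on the log10 scale; by
    the OLS normal equations they sum to zero and are orthogonal to
    log10(mass).
    """
    trait = np.asarray(trait, dtype=float)
    mass = np.asarray(mass, dtype=float)
    if len(trait) < 3:
        raise ValueError("mass correction needs at least 3 fish")
    if np.any(trait <= 0) or np.any(mass <= 0):
        raise ValueError("trait and mass values must be positive for log10")
    x = np.log10(mass)
    y = np.log10(trait)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in body mass: residuals undefined")
    slope, intercept = np.polyfit(x, y, 1)
    return MassCorrection(
        slope=float(slope),
        intercept=float(intercept),
        residuals=y - (intercept + slope * x),
    )


@dataclass
class PCAResult:
    """Correlation-matrix PCA of the secondary metabolic traits."""

    scores: pd.DataFrame  # fish x axes (MET1..)
    loadings: pd.DataFrame  # traits x axes
    explained: np.ndarray  # % variance per axis
    cumulative: np.ndarray  # cumulative %
    eigenvalues: np.ndarray
    dropped_fish: list

    def loadings_report(self, n_axes: int = 3) -> pd.DataFrame:
        """Loading table for the first axes plus cumulative variance row."""
        tab = self.loadings.iloc[:, :n_axes].copy()
        tab.loc["cumulative_variance_pct"] = self.cumulative[:n_axes]
        return tab


def pca_traits(traits: pd.DataFrame, n_axes: int = 3) -> PCAResult:
    """PCA of a per-fish trait matrix via its correlation matrix.

    Columns are centred and scaled to unit (sample, n-1) variance.  Axes are
    ordered by descending eigenvalue; each loading vector is signed so its
    largest-magnitude element is positive.  Fish with any missing trait are
    dropped listwise with a warning.
    """
    df = traits.copy()
    complete = df.dropna()
    dropped = [i for i in df.index if i not in complete.index]
    if dropped:
        logger.warning("PCA: dropped %d fish with missing traits: %s",
                       len(dropped), dropped)
    if len(complete) < 4:
        raise ValueError("PCA needs at least 4 fish with complete traits")
    X = complete.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = complete.columns[sd == 0].tolist()
        raise ValueError(f"constant trait column(s): {bad}")
    Z = (X - X.mean(axis=0)) / sd
    corr = Z.T @ Z / (len(Z) - 1)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    # sign convention: largest-magnitude loading positive
    for j in range(eigvec.shape[1]):
        k = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[k, j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    scores = Z @ eigvec
    explained = 100.0 * eigval / eigval.sum()
    axes = [f"MET{j + 1}" for j in range(len(eigval))]
    return PCAResult(
        scores=pd.DataFrame(scores[:, :n_axes], index=complete.index,
                            columns=axes[:n_axes]),
        loadings=pd.DataFrame(eigvec, index=complete.columns, columns=axes),
        explained=explained,
        cumulative=np.cumsum(explained),
        eigenvalues=eigval,
        dropped_fish=dropped,
    )


def corrected_trait_table(
    traits: pd.DataFrame, phenotypes: pd.DataFrame, n_axes: int = 3
) -> tuple[pd.DataFrame, PCAResult]:
    """Build the per-fish covariate table used by the mixed models.

    Joins the metabolic trait table (one row per fish, see
    :func:`scopetrack.respirometry.traits_table`) with the morphometrics
    table (``fish_id, body_mass_g, fork_length_cm, body_depth_cm``), applies
    the mass correction to SMR/MMR/AMS and the mass-dependent secondary
    traits, computes the fineness ratio, and runs the PCA on the seven
    secondary traits (mass-corrected where applicable, raw otherwise).

    Returns the covariate table (columns ``fl``, ``fr``, ``smr``, ``mmr``,
    ``ams`` as residuals, ``MET1..n``) and the PCA result.
    """
    merged = traits.merge(phenotypes, on="fish_id", how="inner").set_index("fish_id")
    mass = merged["body_mass_g"].to_numpy()
    out = pd.DataFrame(index=merged.index)
    out["fl"] = merged["fork_length_cm"]
    out["fr"] = merged["fork_length_cm"] / merged["body_depth_cm"]

    corrected = {}
    for name in MASS_CORRECTED:
        vals = merged[name].to_numpy(dtype=float)
        ok = np.isfinite(vals) & (vals > 0)
        res = np.full(len(vals), np.nan)
        if ok.sum() >= 3:
            res[ok] = mass_correct(vals[ok], mass[ok]).residuals
        else:
            logger.warning("trait %s: too few positive values for mass correction",
                           name)
        corrected[name] = res
    for key in ("smr", "mmr", "ams"):
        out[key] = corrected[key]

    pca_input = pd.DataFrame(index=merged.index)
    for name in MetabolicTraits.SECONDARY_TRAITS:
        if name in MASS_CORRECTED:
            pca_input[name] = corrected[name]
        else:
            pca_input[name] = merged[name]
    pca = pca_traits(pca_input, n_axes=n_axes)
    out = out.join(pca.scores)
    return out.reset_index(), pca
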