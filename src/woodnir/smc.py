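"""Significant multivariate correlation (sMC) and confounder-aware selection.

sMC scores each spectral variable by decomposing its variance into the
part explained by the PLS regression direction and the residual. With
centred X and regression vector b, the fitted response is y_hat = X_c b
and the projection of X_c onto the b direction is X_hat = y_hat b'/(b'b);
the residual is E = X_c - X_hat. For variable j,

    SSR_j = sum_i X_hat[i, j]^2,   SSE_j = sum_i E[i, j]^2,
    F_j   = (SSR_j / 1) / (SSE_j / (n - 2)),

tested against the F(1, n-2) distribution at level alpha.

The deconfounding rule keeps the wavenumbers that are significant for the
trait (extractives content) and NOT significant for the confounder (grain
angle): the trait-informative region free of confounder influence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .dataset import SpectraSet
from .errors import DegenerateModelError, EmptySelectionError, ValidationError
from .pls import CVResult, PLSModel, fit_pls1, loo_cv


@dataclass
class SMCProfile:
    """Per-wavenumber sMC F statistics with their significance threshold."""

    f_stat: np.ndarray
    df: tuple[int, int]
    alpha: float
    f_crit: float
    significant: np.ndarray
    wavenumbers: np.ndarray | None = None


@dataclass
class DeconfoundSelection:
    """Indices significant for the trait but not for the confounder."""

    selected: list[int]
    trait_profile: SMCProfile
    confounder_profile: SMCProfile
    rule: str = "trait-significant AND NOT confounder-significant"

    @property
    def n_selected(self) -> int:
        return len(self.selected)

    @property
    def wavenumbers(self) -> np.ndarray | None:
        wn = self.trait_profile.wavenumbers
        return None if wn is None else wn[self.selected]


def smc(X: np.ndarray, y: np.ndarray, m: PLSModel, alpha: float = 0.05) -> SMCProfile:
    """sMC importance profile of each column of X for the model's response.

    ``m`` must have been fitted on (X, y); the profile uses the model's
    centring constants and regression vector.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n < 3:
        raise ValidationError(f"sMC needs n >= 3 (got {n})")
    if y.size != n:
        raise ValidationError(f"y has {y.size} entries for {n} rows of X")
    b = m.coef
    if b.size != p:
        raise ValidationError(f"model has {b.size} coefficients for {p} columns")
    bb = float(b @ b)
    if bb == 0:
        raise DegenerateModelError("regression vector is all zeros; sMC undefined")

    Xc = X - m.x_mean
    y_hat = Xc @ b
    # each row of Xc projected onto the b direction: X_hat = y_hat b'/(b'b)
    yy = float(y_hat @ y_hat)
    ssr = yy * b**2 / bb**2  # sum_i (y_hat_i b_j / bb)^2
    # SSE per column from E = Xc - X_hat; the cross term does not vanish
    # columnwise (only in the sum over j), so expand the square explicitly
    cross = (Xc.T @ y_hat) * b / bb
    sse = np.einsum("ij,ij->j", Xc, Xc) - 2.0 * cross + ssr
    sse = np.maximum(sse, 0.0)  # guard tiny negative round-off
    df = (1, n - 2)
    with np.errstate(divide="ignore"):
        f = np.where(sse > 0, ssr / (sse / df[1]), np.where(ssr > 0, np.inf, 0.0))
    f_crit = float(stats.f.ppf(1.0 - alpha, *df))
    return SMCProfile(
        f_stat=f, df=df, alpha=alpha, f_crit=f_crit,
        significant=f > f_crit, wavenumbers=m.wavenumbers,
    )


def select_deconfounded(
    trait: SMCProfile, confounder: SMCProfile, top_k: int | None = None
) -> DeconfoundSelection:
    """Wavenumbers significant for the trait and not for the confounder.

    With ``top_k``, only the top_k such wavenumbers by trait F statistic
    are kept (ties broken toward the lower index); the result is ordered
    by position on the axis.
    """
    if trait.f_stat.size != confounder.f_stat.size:
        raise ValidationError(
            f"profiles computed on different axes ({trait.f_stat.size} vs "
            f"{confounder.f_stat.size} wavenumbers)"
        )
    if (
        trait.wavenumbers is not None
        and confounder.wavenumbers is not None
        and not np.allclose(trait.wavenumbers, confounder.wavenumbers)
    ):
        raise ValidationError("profiles computed on different wavenumber axes")

    keep = np.flatnonzero(trait.significant & ~confounder.significant)
    if keep.size == 0:
        raise EmptySelectionError(
            "no wavenumber is trait-significant and confounder-nonsignificant; "
            "consider raising alpha for the trait or lowering it for the confounder"
        )
    if top_k is not None and top_k < keep.size:
        # stable sort on -F keeps the lower index first among ties
        order = np.argsort(-trait.f_stat[keep], kind="stable")[:top_k]
        keep = np.sort(keep[order])
    return DeconfoundSelection(
        selected=[int(i) for i in keep],
        trait_profile=trait,
        confounder_profile=confounder,
    )


def refit_on_selection(
    s: SpectraSet,
    sel: DeconfoundSelection,
    response: str,
    max_lv: int = 20,
) -> tuple[PLSModel, CVResult]:
    """Refit PLS1 on the selected wavenumbers only.

    Restricts the matrix to the selected columns, chooses the component
    count by leave-one-out CV and fits the final model; the reduced
    wavenumber list is recorded on the model.
    """
    if sel.n_selected == 0:
        raise EmptySelectionError("selection is empty")
    cols = np.asarray(sel.selected, dtype=int)
    X = s.absorbance[:, cols]
    y = s.response(response)
    cv = loo_cv(X, y, max_lv=max_lv)
    model = fit_pls1(X, y, cv.chosen_lv, wavenumbers=s.wavenumbers[cols])
    return model, cv
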