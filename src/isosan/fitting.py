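"""Hill-curve fitting for ISO concentration-response data.

The six dose-response relations all share the saturating Hill form

    y(d) = y_max * d^n / (K^n + d^n)

with n = 1 for all but the I_f-shift relation. This module fits that form
to (dose, response) tables by ordinary least squares on the response scale,
in a statsmodels-like Model/Results shape: ``HillModel(doses, responses)``
with ``fit()`` returning a ``HillFitResults`` carrying estimates, standard
errors and a ``summary()`` table. ``fit_hill`` and ``synthesize_points``
are thin functional wrappers used by the rest of the package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = ["HillModel", "HillFitResults", "NonIdentifiableFit",
           "fit_hill", "synthesize_points", "read_points", "write_points"]


class NonIdentifiableFit(RuntimeError):
    """Degenerate input (e.g. all responses equal): parameters not identifiable."""


def _hill(d, ymax, k, n):
    d = np.asarray(d, dtype=float)
    out = np.zeros_like(d)
    pos = d > 0
    dn = d[pos] ** n
    out[pos] = ymax * dn / (k ** n + dn)
    return out


class HillModel:
    """Saturating dose-response model to be fitted to a point table.

    Parameters
    ----------
    doses : array-like, nM, all >= 0 (at least two distinct positive)
    responses : array-like, same length
    fix_n : float or None
        Fix the Hill coefficient (1.0 for the simple saturation curves);
        None estimates it.
    """

    def __init__(self, doses, responses, *, fix_n: float | None = 1.0):
        self.doses = np.asarray(doses, dtype=float)
        self.responses = np.asarray(responses, dtype=float)
        if self.doses.shape != self.responses.shape or self.doses.ndim != 1:
            raise ValueError("doses and responses must be 1-D and equal length")
        if len(self.doses) < 3:
            raise ValueError("need at least 3 points")
        if np.any(self.doses < 0):
            raise ValueError("doses must be >= 0 nM")
        if len(np.unique(self.doses[self.doses > 0])) < 2:
            raise ValueError("need at least two distinct positive doses")
        self.fix_n = fix_n

    def predict(self, params, doses=None):
        d = self.doses if doses is None else doses
        return _hill(d, *params)

    def fit(self) -> "HillFitResults":
        """Bounded least squares with a deterministic initial-guess rule
        (y_max <- max response, K <- median positive dose, n <- 1)."""
        resp = self.responses
        if np.allclose(resp, resp[0]):
            raise NonIdentifiableFit("all responses equal; curve not identifiable")
        scale = float(np.max(np.abs(resp)))
        sign = 1.0 if np.max(resp) >= abs(np.min(resp)) else -1.0
        y0 = sign * scale
        k0 = float(np.median(self.doses[self.doses > 0]))
        free_n = self.fix_n is None
        x0 = [y0, k0, 1.0] if free_n else [y0, k0]
        lo = [-10 * scale, 1e-9] + ([1e-3] if free_n else [])
        hi = [10 * scale, 1e6] + ([5.0] if free_n else [])

        def resid(x):
            n = x[2] if free_n else self.fix_n
            return _hill(self.doses, x[0], x[1], n) - resp

        sol = least_squares(resid, x0, bounds=(lo, hi), method="trf",
                            xtol=1e-14, ftol=1e-14, gtol=1e-14)
        n_hat = sol.x[2] if free_n else self.fix_n
        params = np.array([sol.x[0], sol.x[1], n_hat])
        dof = max(len(resp) - len(sol.x), 1)
        s2 = float(np.sum(sol.fun ** 2)) / dof
        try:
            cov = s2 * np.linalg.inv(sol.jac.T @ sol.jac)
            bse = np.sqrt(np.diag(cov))
        except np.linalg.LinAlgError:
            bse = np.full(len(sol.x), np.nan)
        if free_n:
            bse_full = bse
        else:
            bse_full = np.append(bse, 0.0)
        return HillFitResults(
            model=self, params=params, bse=bse_full,
            residuals=sol.fun.copy(), ssr=float(np.sum(sol.fun ** 2)),
            n_obs=len(resp), n_free=len(sol.x), success=bool(sol.success),
        )


@dataclass
class HillFitResults:
    """Fitted Hill curve: estimates, uncertainties, diagnostics."""

    model: HillModel
    params: np.ndarray        # [y_max, K_0.5, n]
    bse: np.ndarray           # standard errors (0 for a fixed n)
    residuals: np.ndarray
    ssr: float
    n_obs: int
    n_free: int
    success: bool

    @property
    def ymax(self) -> float:
        return float(self.params[0])

    @property
    def k_half(self) -> float:
        return float(self.params[1])

    @property
    def n(self) -> float:
        return float(self.params[2])

    def predict(self, doses):
        return _hill(np.asarray(doses, dtype=float), *self.params)

    def summary(self) -> str:
        names = ["y_max", "K_0.5 (nM)", "n (Hill)"]
        lines = [
            "Hill dose-response fit (ordinary least squares)",
            f"  observations: {self.n_obs}   free parameters: {self.n_free}"
            f"   SSR: {self.ssr:.6g}",
            f"  {'param':<12}{'estimate':>12}{'std err':>12}",
        ]
        for name, est, se in zip(names, self.params, self.bse):
            se_s = f"{se:>12.4g}" if np.isfinite(se) and se > 0 else f"{'(fixed)':>12}"
            lines.append(f"  {name:<12}{est:>12.5g}{se_s}")
        return "\n".join(lines)


def fit_hill(points, fix_n: float | None = 1.0) -> HillFitResults:
    """Fit the Hill form to a (dose, response) point table.

    `points` is a sequence of (dose_nM, response) pairs or a 2-column array.
    """
    arr = np.asarray(points, dtype=float)
    return HillModel(arr[:, 0], arr[:, 1], fix_n=fix_n).fit()


def synthesize_points(params, doses, noise_sd: float = 0.0, seed=None):
    """Noisy samples of a Hill curve: deterministic for a fixed seed.

    `params` is (y_max, K_0.5) or (y_max, K_0.5, n); noise is additive
    Gaussian on the response.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    params = tuple(params)
    if len(params) == 2:
        params = params + (1.0,)
    doses = np.asarray(doses, dtype=float)
    resp = _hill(doses, *params)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        resp = resp + rng.normal(0.0, noise_sd, size=resp.shape)
    return np.column_stack([doses, resp])


def read_points(path):
    """Read a 2-column delimited text table (one header line)."""
    return np.loadtxt(path, skiprows=1, delimiter=None)


def write_points(path, points, header="dose_nm response"):
    np.savetxt(path, np.asarray(points, dtype=float), header=header, comments="")
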