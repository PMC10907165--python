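"""Model/Results classes for fitting the two binding assays.

The API follows the statsmodels convention: a model object is constructed
from observed data (`ItcModel`, `AnisotropyModel`), its ``fit()`` method
runs nonlinear least squares (via lmfit) and returns a `BindingResults`
object carrying point estimates, standard errors from the local quadratic
approximation, optional residual-resampling bootstrap intervals,
residuals, diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import lmfit
import numpy as np

from .isotherm import (
    AnisotropyMode,
    BindingTruth,
    ItcProtocol,
    anisotropy_model,
    itc_injection_heats,
)

Mode = Literal["ITC", "ANISOTROPY"]


class DegenerateDataError(ValueError):
    """Raised when the data cannot identify the binding parameters at all
    (e.g. all-zero heats, flat anisotropy, too few points)."""


@dataclass(frozen=True)
class TitrationSeries:
    """Observed titration data for either assay.

    ITC mode: ``heats`` (ucal, one per injection) paired with a protocol.
    Anisotropy mode: protein totals ``Pt`` (uM), fixed labelled-peptide
    total ``Lt`` (uM) and anisotropy values ``A``.
    """

    mode: Mode
    heats: tuple[float, ...] | None = None
    protocol: ItcProtocol | None = None
    Pt: tuple[float, ...] | None = None
    Lt: float | None = None
    A: tuple[float, ...] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode == "ITC":
            if self.heats is None or self.protocol is None:
                raise ValueError("ITC series needs heats and a protocol")
            if len(self.heats) != len(self.protocol.injection_volumes):
                raise ValueError(
                    f"{len(self.heats)} heats but protocol has "
                    f"{len(self.protocol.injection_volumes)} injections"
                )
        elif self.mode == "ANISOTROPY":
            if self.Pt is None or self.A is None or self.Lt is None:
                raise ValueError("anisotropy series needs Pt, Lt and A")
            if len(self.Pt) != len(self.A):
                raise ValueError("Pt and A must have equal length")
            if not self.Lt > 0:
                raise ValueError("Lt must be positive")
            if any(p < 0 for p in self.Pt):
                raise ValueError("Pt values must be non-negative")
            if any(b <= a for a, b in zip(self.Pt, self.Pt[1:])):
                import warnings

                warnings.warn("Pt values are not strictly increasing", stacklevel=2)
        else:
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class BindingResults:
    """Fitted binding parameters with uncertainties and diagnostics."""

    model: "ItcModel | AnisotropyModel"
    params: dict[str, float]
    stderr: dict[str, float | None]
    residuals: np.ndarray
    fitted: np.ndarray
    converged: bool
    nfev: int
    chisqr: float
    diagnostics: list[str] = field(default_factory=list)
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_boot: int = 0

    @property
    def Kd(self) -> float:
        return self.params["Kd"]

    def bootstrap_ci(self, n_boot: int = 200, seed: int = 0,
                     level: float = 0.95) -> dict[str, tuple[float, float]]:
        """Residual-resampling bootstrap percentile intervals.

        Resamples residuals with replacement onto the fitted curve, refits,
        and takes percentile intervals. Reproducible under a fixed seed;
        intervals are widened, if necessary, to contain the point estimate.
        """
        if not self.converged:
            raise ValueError("cannot bootstrap a non-converged fit")
        if n_boot < 20:
            raise ValueError("n_boot must be at least 20")
        rng = np.random.default_rng(seed)
        draws: dict[str, list[float]] = {k: [] for k in self.params}
        resid = self.residuals
        for _ in range(n_boot):
            y_star = self.fitted + rng.choice(resid, size=resid.size, replace=True)
            try:
                r = self.model._fit_to(y_star, init=self.params)
            except DegenerateDataError:
                continue
            if r.converged:
                for k, v in r.params.items():
                    draws[k].append(v)
        alpha = (1.0 - level) / 2.0
        out = {}
        for k, vals in draws.items():
            if len(vals) < max(20, n_boot // 2):
                self.diagnostics.append(f"bootstrap unstable for {k}")
            arr = np.asarray(vals if vals else [self.params[k]])
            lo, hi = np.quantile(arr, [alpha, 1 - alpha])
            lo, hi = min(lo, self.params[k]), max(hi, self.params[k])
            out[k] = (float(lo), float(hi))
        self.ci = out
        self.n_boot = n_boot
        return out

    def summary(self) -> str:
        lines = [
            f"{type(self.model).__name__} fit "
            f"({'converged' if self.converged else 'NOT CONVERGED'}, "
            f"nfev={self.nfev}, chi-square={self.chisqr:.4g})",
            "-" * 64,
            f"{'param':>8} {'estimate':>12} {'std err':>10} "
            f"{'95% CI' if self.ci else '':>22}",
        ]
        for k, v in self.params.items():
            se = self.stderr.get(k)
            se_s = f"{se:10.4g}" if se is not None else f"{'--':>10}"
            ci_s = (
                f"[{self.ci[k][0]:.4g}, {self.ci[k][1]:.4g}]" if k in self.ci else ""
            )
            lines.append(f"{k:>8} {v:12.5g} {se_s} {ci_s:>22}")
        if self.diagnostics:
            lines.append("-" * 64)
            lines += [f"note: {d}" for d in self.diagnostics]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "params": self.params,
            "stderr": self.stderr,
            "ci": {k: list(v) for k, v in self.ci.items()},
            "converged": self.converged,
            "chisqr": self.chisqr,
            "residual_norm": float(np.linalg.norm(self.residuals)),
            "diagnostics": self.diagnostics,
        }


class _BaseBindingModel:
    """Shared lmfit machinery for the two assay models."""

    param_names: tuple[str, ...]

    def _observed(self) -> np.ndarray:
        raise NotImplementedError

    def _predict(self, **params) -> np.ndarray:
        raise NotImplementedError

    def _initial_candidates(self) -> list[dict[str, float]]:
        raise NotImplementedError

    def _make_params(self, init: dict[str, float]) -> lmfit.Parameters:
        raise NotImplementedError

    def fit(self, init: dict[str, float] | BindingTruth | None = None) -> BindingResults:
        """Nonlinear least-squares fit; multi-start over default initial
        guesses unless ``init`` is supplied."""
        y = self._observed()
        self._check_identifiable(y)
        if isinstance(init, BindingTruth):
            init = {k: getattr(init, k) for k in self.param_names}
        return self._fit_to(y, init)

    def _fit_to(self, y: np.ndarray, init: dict[str, float] | None) -> BindingResults:
        candidates = (
            [dict(init)] if init is not None else self._initial_candidates()
        )
        best = None
        for cand in candidates:
            params = self._make_params(cand)

            def resid(p):
                return self._predict(**{k: p[k].value for k in self.param_names}) - y

            try:
                res = lmfit.minimize(resid, params, method="leastsq")
            except Exception:
                continue
            if best is None or res.chisqr < best.chisqr:
                best = res
        if best is None:
            raise DegenerateDataError("no fit attempt converged")
        est = {k: float(best.params[k].value) for k in self.param_names}
        stderr = {
            k: (float(best.params[k].stderr) if best.params[k].stderr else None)
            for k in self.param_names
        }
        fitted = self._predict(**est)
        diagnostics: list[str] = []
        for k in self.param_names:
            p = best.params[k]
            for bound in (p.min, p.max):
                if math.isfinite(bound) and bound != 0 and abs(p.value - bound) < 1e-8 * max(1.0, abs(bound)):
                    diagnostics.append(f"parameter {k} pinned at bound {bound:g}")
        converged = bool(best.success)
        if not converged:
            diagnostics.append(f"optimizer did not converge: {best.message}")
        return BindingResults(
            model=self,
            params=est,
            stderr=stderr if converged else {k: None for k in self.param_names},
            residuals=np.asarray(fitted - y),
            fitted=np.asarray(fitted),
            converged=converged,
            nfev=best.nfev,
            chisqr=float(best.chisqr),
            diagnostics=diagnostics,
        )

    def _check_identifiable(self, y: np.ndarray) -> None:
        raise NotImplementedError


class ItcModel(_BaseBindingModel):
    """Single-site ITC isotherm with fitted stoichiometry.

    Parameters are Kd (uM), n (injectant sites per cell macromolecule; the
    2:1 ExbD:D-box complex corresponds to n = 0.5) and dH (kcal/mol). The
    first injection is excluded from the objective by default, as is
    conventional for displacement cells whose syringe tip exchanges
    material before the run starts.
    """

    param_names = ("Kd", "n", "dH")

    def __init__(self, series: TitrationSeries, skip_first: bool = True,
                 fix_n: float | None = None):
        if series.mode != "ITC":
            raise ValueError("ItcModel requires an ITC-mode series")
        usable = len(series.heats) - (1 if skip_first else 0)
        if usable < 5:
            raise DegenerateDataError(
                f"need >= 5 usable injections, have {usable}"
            )
        self.series = series
        self.skip_first = skip_first
        self.fix_n = fix_n
        self._mask = np.ones(len(series.heats), dtype=bool)
        if skip_first:
            self._mask[0] = False

    @classmethod
    def from_dataframe(cls, frame, protocol: ItcProtocol, **kw) -> "ItcModel":
        """Build from a DataFrame with a ``heat_ucal`` column (one row per
        injection, in order)."""
        heats = tuple(float(h) for h in frame["heat_ucal"])
        return cls(TitrationSeries("ITC", heats=heats, protocol=protocol), **kw)

    def _observed(self) -> np.ndarray:
        return np.asarray(self.series.heats)[self._mask]

    def _predict(self, Kd, n, dH) -> np.ndarray:
        q = itc_injection_heats(
            BindingTruth(Kd=Kd, n=n, dH=dH), self.series.protocol
        )
        return q[self._mask]

    def _check_identifiable(self, y: np.ndarray) -> None:
        if np.allclose(y, 0.0, atol=1e-12):
            raise DegenerateDataError(
                "all injection heats are zero: no detectable binding, "
                "parameters not estimable"
            )

    def _initial_candidates(self) -> list[dict[str, float]]:
        proto = self.series.protocol
        q1 = self._observed()[0]
        # assume the first usable injection binds most of what it delivers
        dX = proto.syringe_concentration * proto.injection_volumes[0] / proto.cell_volume
        dH0 = q1 / (proto.cell_volume * dX * 1e-3)
        n0 = 1.0 if self.fix_n is None else self.fix_n
        grid = [proto.cell_concentration * f for f in (0.02, 0.2, 1.0, 5.0)]
        return [{"Kd": kd, "n": n0, "dH": dH0} for kd in grid]

    def _make_params(self, init: dict[str, float]) -> lmfit.Parameters:
        p = lmfit.Parameters()
        p.add("Kd", value=max(init.get("Kd", 10.0), 1e-4), min=1e-4, max=1e6)
        p.add("n", value=init.get("n", 1.0), min=1e-3, max=100.0,
              vary=self.fix_n is None)
        if self.fix_n is not None:
            p["n"].value = self.fix_n
        p.add("dH", value=init.get("dH", -1.0), min=-1e3, max=1e3)
        return p


class AnisotropyModel(_BaseBindingModel):
    """Fluorescence-anisotropy titration of a fixed labelled peptide.

    Fits (Kd, A0, Amax) with the labelled-peptide total Lt held at its
    experimental value; the exact ligand-depletion quadratic is used, so
    the fit remains valid when the protein series approaches Lt.
    """

    param_names = ("Kd", "A0", "Amax")

    def __init__(self, series: TitrationSeries, mode: AnisotropyMode = "corrected"):
        if series.mode != "ANISOTROPY":
            raise ValueError("AnisotropyModel requires an anisotropy-mode series")
        if len(series.Pt) < 6:
            raise DegenerateDataError(
                f"need >= 6 titration points, have {len(series.Pt)}"
            )
        self.series = series
        self.mode = mode

    @classmethod
    def from_dataframe(cls, frame, Lt: float, **kw) -> "AnisotropyModel":
        """Build from a DataFrame with ``Pt_uM`` and ``anisotropy`` columns."""
        series = TitrationSeries(
            "ANISOTROPY",
            Pt=tuple(float(p) for p in frame["Pt_uM"]),
            Lt=Lt,
            A=tuple(float(a) for a in frame["anisotropy"]),
        )
        return cls(series, **kw)

    def _observed(self) -> np.ndarray:
        return np.asarray(self.series.A)

    def _predict(self, Kd, A0, Amax) -> np.ndarray:
        return anisotropy_model(
            np.asarray(self.series.Pt), self.series.Lt, A0, Amax, Kd, self.mode
        )

    def _check_identifiable(self, y: np.ndarray) -> None:
        if np.ptp(y) < 1e-12:
            raise DegenerateDataError(
                "anisotropy is flat across the titration: Kd unidentifiable"
            )

    def _initial_candidates(self) -> list[dict[str, float]]:
        y = self._observed()
        Pt = np.asarray(self.series.Pt)
        A0, Amax = float(y.min()), float(y.max())
        # inflection guess: Pt where A crosses the midpoint
        mid = 0.5 * (A0 + Amax)
        above = np.nonzero(y >= mid)[0]
        kd0 = float(Pt[above[0]]) if above.size and Pt[above[0]] > 0 else float(np.median(Pt[Pt > 0]))
        return [
            {"Kd": kd, "A0": A0, "Amax": Amax}
            for kd in {kd0, kd0 * 10.0, max(kd0 / 10.0, 1e-3)}
        ]

    def _make_params(self, init: dict[str, float]) -> lmfit.Parameters:
        p = lmfit.Parameters()
        p.add("Kd", value=max(init.get("Kd", 1.0), 1e-4), min=1e-4, max=1e6)
        p.add("A0", value=init.get("A0", 0.0), min=-1.0, max=1.0)
        p.add("Amax", value=init.get("Amax", 0.3), min=-1.0, max=1.0)
        return p


def fit_itc(series: TitrationSeries, init=None, *, fix_n: float | None = None,
            skip_first: bool = True) -> BindingResults:
    """Convenience wrapper: fit an ITC series (see `ItcModel`)."""
    return ItcModel(series, skip_first=skip_first, fix_n=fix_n).fit(init)


def fit_anisotropy(series: TitrationSeries, init=None,
                   mode: AnisotropyMode = "corrected") -> BindingResults:
    """Convenience wrapper: fit an anisotropy series (see `AnisotropyModel`)."""
    return AnisotropyModel(series, mode=mode).fit(init)
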