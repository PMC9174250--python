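"""Coefficient estimation: differential evolution on the AARD% objective.

The estimation problem is a nonlinear regression: given one drug's
measurements (T_i, P_i, rho_i, y2_i) and a correlation from the catalogue,
find the coefficient vector minimizing

    AARD% = (100/N) * sum_i |y2_i - y2_cal_i| / y2_i.

The objective is non-smooth and the correlations can be multi-modal in
their coefficients, so a population-based global optimizer (differential
evolution, DE/rand/1/bin) does the heavy lifting, followed by a
derivative-free Nelder-Mead polish.  Coefficient vectors that produce
non-finite or non-positive mole fractions are not errors: each offending
record contributes a fixed large penalty so the objective is total and
DE simply steers away from them.

Usage follows the Model/Results convention::

    model = SolubilityModel(dataset, correlation="modified_arrhenius")
    res = model.fit(bounds=..., seed=1)
    print(res.summary())
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize

from . import metrics
from .correlations import (
    _FORMS,
    CoefficientSet,
    ConfigurationError,
    chrastil_mass_to_mole,
    evaluate_y2,
    get_spec,
)
from .data import SolubilityDataset
from .diagnostics import (
    hat_values,
    leverage_design,
    standardized_residuals,
    williams_classify,
)

__all__ = [
    "DEConfig",
    "SolubilityModel",
    "SolubilityResults",
    "FitFailure",
    "objective",
    "default_bounds",
    "fit_all",
]

#: Penalty one non-physical record contributes to the AARD sum (percent).
PENALTY = 1.0e6


@dataclass(frozen=True)
class DEConfig:
    """Differential-evolution settings (DE/rand/1/bin).

    ``popsize`` is the population multiplier per coefficient (total
    population = popsize * n_coeff).  Early stopping triggers when the
    relative change of the best objective over ``patience`` generations
    drops below ``tol``.  ``restarts`` independent runs (seeds seed,
    seed+1, ...) are performed and the best kept.
    """

    popsize: int = 15
    mutation: float = 0.8
    recombination: float = 0.9
    generations: int = 2000
    tol: float = 1e-10
    patience: int = 200
    restarts: int = 5
    seed: int = 42
    polish: bool = True

    def __post_init__(self):
        if self.popsize < 4:
            raise ValueError("popsize multiplier must be >= 4")
        if not 0 < self.mutation <= 2:
            raise ValueError("mutation factor must be in (0, 2]")
        if not 0 <= self.recombination <= 1:
            raise ValueError("crossover rate must be in [0, 1]")
        if self.generations < 1 or self.restarts < 1:
            raise ValueError("generations and restarts must be positive")


def default_bounds(model_id: str):
    """Default coefficient box: [-1e5, 1e5] each; the modified Arrhenius
    decay coefficient a4 is restricted to [0, 1e4] (exponential decay in
    inverse pressure)."""
    spec = get_spec(model_id)
    bounds = [(-1e5, 1e5)] * spec.n_coeff
    if model_id == "modified_arrhenius":
        bounds[3] = (0.0, 1e4)
    return bounds


def objective(model_id, a, dataset: SolubilityDataset, mw_drug=None,
              penalty: float = PENALTY) -> float:
    """AARD% of a coefficient vector on a dataset (total: never NaN/inf).

    Records whose prediction is non-finite or <= 0 each contribute
    ``penalty`` (instead of 100*|RD|) to the averaged sum.
    """
    y_cal = np.asarray(
        evaluate_y2(model_id, a, dataset.T, dataset.P, dataset.rho,
                    mw_drug=mw_drug),
        dtype=float,
    )
    ok = np.isfinite(y_cal) & (y_cal > 0)
    dev = np.where(
        ok, 100.0 * np.abs(dataset.y2 - np.where(ok, y_cal, 1.0)) / dataset.y2,
        penalty,
    )
    return float(np.mean(dev))


def _init_population(rng, bounds, n_pop):
    """Initial DE population, log-uniform in coefficient magnitude.

    Correlation coefficients span many orders of magnitude (mole-fraction
    scale terms are ~1e-6 while exponential-decay terms are ~1e1), so a
    uniform draw over a wide box starts the whole population in the
    non-physical penalty region.  Half the population is drawn uniformly
    over the box, half log-uniformly in magnitude down to 1e-10 of the
    box half-width, with random sign where the box straddles zero.
    """
    k = len(bounds)
    pop = np.empty((n_pop, k))
    uniform_rows = n_pop // 2
    for j, (lo, hi) in enumerate(bounds):
        u = rng.uniform(lo, hi, size=uniform_rows)
        span = max(abs(lo), abs(hi))
        mag = 10.0 ** rng.uniform(np.log10(span) - 10.0, np.log10(span),
                                  size=n_pop - uniform_rows)
        if lo < 0 < hi:
            vals = rng.choice([-1.0, 1.0], size=mag.size) * mag
        elif hi <= 0:
            vals = -mag
        else:
            vals = mag
        pop[:, j] = np.concatenate([u, np.clip(vals, lo, hi)])
    return pop


class _Monitor:
    """Records the per-generation best objective and stops on stagnation."""

    def __init__(self, tol: float, patience: int):
        self.tol = tol
        self.patience = patience
        self.trace: list[float] = []

    def __call__(self, intermediate_result):
        best = float(intermediate_result.fun)
        if self.trace:
            best = min(best, self.trace[-1])
        self.trace.append(best)
        if len(self.trace) > self.patience:
            prev = self.trace[-self.patience - 1]
            if prev - best <= self.tol * max(abs(best), 1e-300):
                raise StopIteration


class SolubilityModel:
    """One drug's solubility data bound to one catalogue correlation.

    Parameters
    ----------
    dataset : SolubilityDataset
        The measurements; ``nobs`` must be at least the correlation's
        coefficient count.
    correlation : str
        Catalogue identifier (default the modified Arrhenius form).
    molar_mass : float, optional
        Drug molar mass in kg/kmol.  Required for Chrastil, whose native
        output (mass per volume) must be converted to mole fraction to be
        scored against y2 data.
    """

    def __init__(self, dataset: SolubilityDataset,
                 correlation: str = "modified_arrhenius",
                 molar_mass: float | None = None):
        self.spec = get_spec(correlation)
        self.correlation = correlation
        self.dataset = dataset
        self.molar_mass = molar_mass
        if self.spec.output_space == "mass_per_volume_c2" and molar_mass is None:
            raise ConfigurationError(
                f"{correlation} predicts mass-per-volume; a drug molar_mass "
                "is required to fit it against mole-fraction data"
            )
        if dataset.nobs < self.spec.n_coeff:
            raise ValueError(
                f"{dataset.nobs} records cannot identify "
                f"{self.spec.n_coeff} coefficients"
            )

    @classmethod
    def from_dataframe(cls, df, correlation: str = "modified_arrhenius",
                       drug_id: str | None = None, **kwargs):
        return cls(SolubilityDataset.from_dataframe(df, drug_id=drug_id),
                   correlation, **kwargs)

    def predict(self, params, T=None, P=None, rho=None):
        """Mole-fraction predictions at the data (default) or given points."""
        if T is None:
            T, P, rho = self.dataset.T, self.dataset.P, self.dataset.rho
        return evaluate_y2(self.correlation, params, T, P, rho,
                           mw_drug=self.molar_mass)

    def objective(self, params) -> float:
        """AARD% of a candidate coefficient vector on the bound data."""
        return objective(self.correlation, params, self.dataset,
                         mw_drug=self.molar_mass)

    def _population_objective(self):
        """Objective evaluating a whole DE population at once.

        Returns a callable taking coefficients of shape (k,) or (k, S)
        and returning the AARD% as a scalar or an (S,) vector.  Every
        catalogue form is elementwise in its coefficients, so population
        evaluation is plain numpy broadcasting: coefficient rows (S,)
        against data columns (N, 1).
        """
        ds = self.dataset
        T, P, rho = ds.T[:, None], ds.P[:, None], ds.rho[:, None]
        y_exp = ds.y2[:, None]
        form = _FORMS[self.correlation]
        convert = self.spec.output_space == "mass_per_volume_c2"
        mw = self.molar_mass

        def fun(a):
            a = np.asarray(a, dtype=float)
            scalar = a.ndim == 1
            if scalar:
                a = a[:, None]
            with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
                y_cal = form(a[:, None, :], T, P, rho)  # (N, S)
                if convert:
                    y_cal = chrastil_mass_to_mole(y_cal, rho, mw)
            ok = np.isfinite(y_cal) & (y_cal > 0)
            dev = np.where(
                ok,
                100.0 * np.abs(y_exp - np.where(ok, y_cal, 1.0)) / y_exp,
                PENALTY,
            )
            out = dev.mean(axis=0)
            return float(out[0]) if scalar else out

        return fun

    def fit(self, config: DEConfig | None = None, bounds=None,
            **config_overrides) -> "SolubilityResults":
        """Estimate coefficients by best-of-restarts differential evolution.

        Parameters
        ----------
        config : DEConfig, optional
            Optimizer settings; keyword overrides (e.g. ``seed=7``,
            ``restarts=1``) are applied on top.
        bounds : sequence of (lo, hi), optional
            Per-coefficient box; defaults to :func:`default_bounds`.
        """
        config = config or DEConfig()
        if config_overrides:
            config = replace(config, **config_overrides)
        if bounds is None:
            bounds = default_bounds(self.correlation)
        bounds = [(float(lo), float(hi)) for lo, hi in bounds]
        if len(bounds) != self.spec.n_coeff:
            raise ValueError(
                f"{self.spec.n_coeff} bounds required, got {len(bounds)}"
            )
        for lo, hi in bounds:
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError("bounds must be finite with lo < hi")

        pop_objective = self._population_objective()
        best = None
        best_trace = None
        best_seed = None
        n_pop = config.popsize * self.spec.n_coeff
        for i in range(config.restarts):
            seed_i = int((config.seed + i) % (2**31 - 1))
            init = _init_population(np.random.default_rng(seed_i), bounds,
                                    n_pop)
            monitor = _Monitor(config.tol, config.patience)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                res = optimize.differential_evolution(
                    pop_objective,
                    bounds,
                    strategy="rand1bin",
                    maxiter=config.generations,
                    popsize=config.popsize,
                    tol=0.0,
                    mutation=config.mutation,
                    recombination=config.recombination,
                    seed=seed_i,
                    init=init,
                    polish=False,
                    vectorized=True,
                    updating="deferred",
                    callback=monitor,
                )
            x_i, f_i = res.x, float(res.fun)
            if config.polish:
                # Nelder-Mead handles the |.| kinks of the AARD surface
                # that a quasi-Newton polish would stumble on near an
                # exact fit.
                pol = optimize.minimize(
                    self.objective, x_i, method="Nelder-Mead",
                    options={"xatol": 1e-14, "fatol": 1e-14, "maxiter": 4000},
                )
                lo = np.array([b[0] for b in bounds])
                hi = np.array([b[1] for b in bounds])
                x_pol = np.clip(pol.x, lo, hi)
                f_pol = self.objective(x_pol)
                if f_pol < f_i:
                    x_i, f_i = x_pol, f_pol
            if best is None or f_i < best[1]:
                best = (x_i, f_i)
                best_trace, best_seed = monitor.trace, seed_i

        x, fun = best
        y_best = np.asarray(self.predict(x), dtype=float)
        if not np.any(np.isfinite(y_best) & (y_best > 0)):
            raise RuntimeError(
                "the best DE candidate predicts no physical (positive, "
                "finite) solubility at any record; widen the coefficient "
                "bounds"
            )

        coeffs = CoefficientSet(self.correlation, self.dataset.drug_id,
                                tuple(x), provenance="fitted")
        return SolubilityResults(
            model=self, coeffs=coeffs, aard=fun,
            trace=tuple(best_trace), seed_used=best_seed, config=config,
            bounds=tuple(bounds),
        )


@dataclass(frozen=True)
class SolubilityResults:
    """Fit outcome: coefficients, quality metrics and the optimizer trace."""

    model: SolubilityModel
    coeffs: CoefficientSet
    aard: float
    trace: tuple
    seed_used: int
    config: DEConfig
    bounds: tuple
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def params(self) -> np.ndarray:
        return np.asarray(self.coeffs.a)

    @property
    def nobs(self) -> int:
        return self.model.dataset.nobs

    @property
    def fittedvalues(self) -> np.ndarray:
        if "fitted" not in self._cache:
            self._cache["fitted"] = np.asarray(self.model.predict(self.params))
        return self._cache["fitted"]

    @property
    def resid(self) -> np.ndarray:
        return self.model.dataset.y2 - self.fittedvalues

    @property
    def relative_deviations(self) -> np.ndarray:
        return metrics.relative_deviations(self.model.dataset.y2,
                                           self.fittedvalues)

    @property
    def rsquared(self) -> float:
        return metrics.r2(self.model.dataset.y2, self.fittedvalues)

    @property
    def std_error(self) -> float:
        return metrics.std_error(self.model.dataset.y2, self.fittedvalues)

    def predict(self, T=None, P=None, rho=None):
        return self.model.predict(self.params, T, P, rho)

    def leverage_report(self, design=None, sr_limit: float = 3.0):
        """Williams-plot outlier classification of the fitted records."""
        if design is None:
            design = leverage_design(self.model.dataset)
        design = np.asarray(design, dtype=float)
        hat = hat_values(design)
        sr = standardized_residuals(self.model.dataset.y2, self.fittedvalues)
        return williams_classify(sr, hat, k=design.shape[1] - 1,
                                 sr_limit=sr_limit)

    def to_dict(self) -> dict:
        return {
            "model": self.coeffs.model_id,
            "drug": self.coeffs.drug_id,
            "coefficients": list(self.coeffs.a),
            "provenance": self.coeffs.provenance,
            "aard_pct": self.aard,
            "r2": self.rsquared,
            "std_error": self.std_error,
            "n": self.nobs,
            "seed_used": self.seed_used,
            "generations_run": len(self.trace),
            "bounds": [list(b) for b in self.bounds],
            "config": {
                "popsize": self.config.popsize,
                "mutation": self.config.mutation,
                "recombination": self.config.recombination,
                "generations": self.config.generations,
                "tol": self.config.tol,
                "patience": self.config.patience,
                "restarts": self.config.restarts,
                "seed": self.config.seed,
            },
        }

    def to_json(self, path=None, **kwargs) -> str:
        text = json.dumps(self.to_dict(), indent=2, **kwargs)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text

    def summary(self) -> str:
        ds = self.model.dataset
        lines = [
            "Solubility correlation fit (differential evolution)",
            "=" * 55,
            f"Correlation:    {self.coeffs.model_id:<24} N: {self.nobs}",
            f"Drug:           {self.coeffs.drug_id}",
            f"AARD%:          {self.aard:<24.4f} R2: {self.rsquared:.5f}",
            f"Std. error:     {self.std_error:<24.4e} seed: {self.seed_used}",
            f"Restarts:       {self.config.restarts:<24d} "
            f"generations: {len(self.trace)}",
            f"T range (K):    {ds.T.min():g}-{ds.T.max():g}    "
            f"P range (MPa): {ds.P.min():g}-{ds.P.max():g}",
            "-" * 55,
            "Coefficients (natural units):",
        ]
        for i, a in enumerate(self.coeffs.a, start=1):
            lines.append(f"  a{i}: {a: .10e}")
        lines.append("=" * 55)
        return "\n".join(lines)

    # -- plotting ---------------------------------------------------------

    def plot_parity(self, ax=None):
        """Experimental vs calculated mole fraction on log-log axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        y_exp, y_cal = self.model.dataset.y2, self.fittedvalues
        ax.loglog(y_exp, y_cal, "o", mfc="none")
        lims = [min(y_exp.min(), y_cal.min()), max(y_exp.max(), y_cal.max())]
        ax.plot(lims, lims, "k--", lw=1)
        ax.set_xlabel(r"$y_2$ experimental")
        ax.set_ylabel(r"$y_2$ calculated")
        ax.set_title(f"{self.coeffs.drug_id}: AARD = {self.aard:.2f}%")
        return ax

    def plot_williams(self, ax=None, design=None):
        """Williams plot: standardized residual vs leverage, with limits."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        rep = self.leverage_report(design=design)
        valid = rep.flags == "valid"
        ax.plot(rep.hat[valid], rep.sr[valid], "s", mfc="none", label="valid")
        if (~valid).any():
            ax.plot(rep.hat[~valid], rep.sr[~valid], "o", label="suspect")
        ax.axhline(rep.sr_limit, color="k", ls=":", lw=1)
        ax.axhline(-rep.sr_limit, color="k", ls=":", lw=1)
        ax.axvline(rep.hat_limit, color="k", ls="--", lw=1)
        ax.set_xlabel("hat value")
        ax.set_ylabel("standardized residual")
        ax.legend()
        return ax


@dataclass(frozen=True)
class FitFailure:
    """Diagnosed failure of one (drug, correlation) cell of a fit matrix."""

    drug_id: str
    model_id: str
    reason: str


def fit_all(datasets, models=None, config: DEConfig | None = None,
            bounds=None, molar_masses=None):
    """Fit every (drug, correlation) pair; failures are recorded, not fatal.

    Parameters
    ----------
    datasets : mapping drug_id -> SolubilityDataset
    models : sequence of correlation ids (must be nonempty)
    config : DEConfig shared by all fits
    bounds : optional mapping model_id -> bounds box
    molar_masses : optional mapping drug_id -> kg/kmol (enables Chrastil)

    Returns
    -------
    dict mapping (drug_id, model_id) -> SolubilityResults or FitFailure.
    """
    if models is None:
        models = ["modified_arrhenius"]
    models = list(models)
    if not models:
        raise ConfigurationError("empty correlation list")
    molar_masses = molar_masses or {}
    out = {}
    for drug, ds in datasets.items():
        for mid in models:
            try:
                m = SolubilityModel(ds, mid, molar_mass=molar_masses.get(drug))
                b = bounds.get(mid) if isinstance(bounds, dict) else bounds
                out[(drug, mid)] = m.fit(config=config, bounds=b)
            except (ConfigurationError, ValueError, RuntimeError) as exc:
                warnings.warn(f"fit failed for ({drug}, {mid}): {exc}")
                out[(drug, mid)] = FitFailure(drug, mid, str(exc))
    return out
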