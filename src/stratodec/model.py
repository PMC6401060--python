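"""DECModel / DECResults: maximum-likelihood fitting and model comparison.

The entry point mirrors the familiar model/results idiom: build a
:class:`DECModel` from a dated tree, a tip range table and a geographic
scenario, call :meth:`DECModel.fit`, and read estimates, uncertainties and
diagnostics off the returned :class:`DECResults`.  ``compare_models`` fits
a set of dispersal hypotheses (by default the six corridor x dispersal-mode
combinations A-F) on the same data and tabulates −ln L, dispersal and
extinction per model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats

from .geography import MODEL_SPECS, DispersalModelSpec, Geography
from .likelihood import DECEngine, DECParameters, ZeroLikelihoodError
from .phylo import Phylogeny

logger = logging.getLogger(__name__)

__all__ = ["DECModel", "DECResults", "fit_dec", "compare_models", "ModelComparison"]

#: Fixed multi-start grid on (d, e), chosen to bracket plausible island
#: rate magnitudes (events per My).  Fixed, so fits are deterministic.
DEFAULT_STARTS = (
    (0.005, 0.002),
    (0.05, 0.02),
    (0.001, 0.01),
    (0.1, 0.001),
)

#: Box bounds for the rates during optimisation (log scale inside).
RATE_BOUNDS = (1e-9, 10.0)

_ZERO_PENALTY = 1e12


def _coerce_ranges(tip_ranges, geography: Geography) -> dict[str, int]:
    """Accept a dict of bitmasks, a TipRangeTable, or a 0/1 DataFrame."""
    if hasattr(tip_ranges, "masks"):  # TipRangeTable
        return dict(tip_ranges.masks)
    if isinstance(tip_ranges, pd.DataFrame):
        cols = list(tip_ranges.columns)
        if cols != geography.labels:
            raise ValueError(
                f"range-table columns {cols} do not match geography areas "
                f"{geography.labels}"
            )
        out = {}
        for taxon, row in tip_ranges.iterrows():
            mask = 0
            for i, v in enumerate(row.to_numpy()):
                if v:
                    mask |= 1 << i
            out[str(taxon)] = mask
        return out
    return dict(tip_ranges)


class DECModel:
    """A time-stratified DEC model bound to one dataset and one hypothesis.

    Parameters
    ----------
    tree : Phylogeny
        Rooted ultrametric dated tree, ages in My.
    tip_ranges : dict | TipRangeTable | DataFrame
        Taxon -> occupied-area bitmask (or a 0/1 table with one column per
        area in geography order).
    geography : Geography
        Areas, events, distances and corridors.
    spec : DispersalModelSpec | str
        The dispersal hypothesis; a letter A-F selects the canonical set.
    max_range_size : int, optional
        Cap on range occupancy to bound the state space for many areas.
    """

    def __init__(
        self,
        tree: Phylogeny,
        tip_ranges,
        geography: Geography,
        spec: DispersalModelSpec | str = "B",
        max_range_size: int | None = None,
    ):
        if isinstance(spec, str):
            spec = MODEL_SPECS[spec]
        self.tree = tree
        self.geography = geography
        self.spec = spec
        self.tip_ranges = _coerce_ranges(tip_ranges, geography)
        for taxon, mask in self.tip_ranges.items():
            if mask == 0:
                raise ValueError(f"tip {taxon!r} has an empty range")
        self.max_range_size = max_range_size
        self.engine = DECEngine(
            tree, self.tip_ranges, geography, spec, max_range_size
        )

    @classmethod
    def from_files(
        cls,
        tree_path,
        ranges_path,
        geography: Geography | None = None,
        config_path=None,
        spec: DispersalModelSpec | str = "B",
        dialect: str = "auto",
        max_range_size: int | None = None,
        strip_whitespace: bool = False,
    ) -> "DECModel":
        """Build a model from a Newick file and a range-table file."""
        from . import io as wio

        if geography is None:
            if config_path is None:
                raise ValueError("provide either a Geography or a config_path")
            geography = wio.load_geography(config_path)
        tree = wio.read_tree(tree_path)
        table = wio.read_ranges(
            ranges_path, geography.labels, dialect=dialect,
            strip_whitespace=strip_whitespace,
        )
        table.validate_against(tree)
        return cls(tree, table, geography, spec, max_range_size)

    # -- likelihood ------------------------------------------------------

    def loglike(self, params: DECParameters | tuple) -> float:
        if not isinstance(params, DECParameters):
            params = DECParameters(*params)
        return self.engine.loglike(params)

    def _objective(self, x: np.ndarray) -> float:
        try:
            return -self.engine.loglike(DECParameters(np.exp(x[0]), np.exp(x[1])))
        except ZeroLikelihoodError:
            return _ZERO_PENALTY

    # -- fitting ---------------------------------------------------------

    def fit(
        self,
        starts=DEFAULT_STARTS,
        bounds=RATE_BOUNDS,
        tol: float = 1e-8,
        maxiter: int = 500,
    ) -> "DECResults":
        """Maximise ln L over (d, e) on the log scale.

        Bounded L-BFGS-B from each start of a fixed grid; the best optimum
        wins.  Deterministic given the configuration: refitting the same
        model yields the identical result.
        """
        log_bounds = [(np.log(bounds[0]), np.log(bounds[1]))] * 2
        best = None
        n_iter = 0
        for d0, e0 in starts:
            x0 = np.log([d0, e0])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                res = scipy.optimize.minimize(
                    self._objective,
                    x0,
                    method="L-BFGS-B",
                    bounds=log_bounds,
                    options={"maxiter": maxiter, "ftol": tol, "gtol": 1e-8},
                )
            n_iter += res.nit
            if best is None or res.fun < best.fun:
                best = res
        if best.fun >= _ZERO_PENALTY:
            raise ZeroLikelihoodError(
                "all optimisation starts hit a zero-likelihood region; the data "
                "are infeasible under this geography/model"
            )
        if not best.success:
            # L-BFGS-B occasionally reports abnormal termination near flat
            # optima; a derivative-free polish from the same point usually
            # settles it without changing the optimum.
            polish = scipy.optimize.minimize(
                self._objective,
                best.x,
                method="Nelder-Mead",
                options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 400},
            )
            n_iter += polish.nit
            if polish.fun <= best.fun:
                best = polish
            best.x = np.clip(best.x, log_bounds[0][0], log_bounds[0][1])
        converged = bool(best.success)
        if not converged:
            logger.warning(
                "DEC fit for model %s did not converge: %s", self.spec.id, best.message
            )
        d_hat, e_hat = np.exp(best.x)
        params = DECParameters(float(d_hat), float(e_hat))
        at_lower = bool(np.any(np.isclose(best.x, np.log(bounds[0]), atol=1e-6)))
        bse = self._param_se(best.x)
        return DECResults(
            model=self,
            spec=self.spec,
            params=params,
            neg_ln_L=float(best.fun),
            converged=converged,
            n_iter=int(n_iter),
            n_starts=len(starts),
            at_bound=at_lower,
            bse_log=bse,
        )

    def _param_se(self, x_opt: np.ndarray) -> np.ndarray:
        """Approximate standard errors of (log d, log e) from the Hessian."""
        h = 1e-4
        H = np.zeros((2, 2))
        f0 = self._objective(x_opt)
        try:
            for i in range(2):
                for j in range(i, 2):
                    ei = np.eye(2)[i] * h
                    ej = np.eye(2)[j] * h
                    H[i, j] = H[j, i] = (
                        self._objective(x_opt + ei + ej)
                        - self._objective(x_opt + ei - ej)
                        - self._objective(x_opt - ei + ej)
                        + self._objective(x_opt - ei - ej)
                    ) / (4 * h * h)
            cov = np.linalg.inv(H)
            var = np.diag(cov)
            if np.any(var <= 0) or not np.all(np.isfinite(var)):
                return np.full(2, np.nan)
            return np.sqrt(var)
        except np.linalg.LinAlgError:
            return np.full(2, np.nan)


@dataclass
class DECResults:
    """Fitted rates, likelihood and diagnostics for one DEC model."""

    model: DECModel
    spec: DispersalModelSpec
    params: DECParameters
    neg_ln_L: float
    converged: bool
    n_iter: int
    n_starts: int
    at_bound: bool = False
    bse_log: np.ndarray = field(default_factory=lambda: np.full(2, np.nan))

    @property
    def lnL(self) -> float:
        return -self.neg_ln_L

    def rate_ci(self, alpha: float = 0.05) -> dict[str, tuple[float, float]]:
        """Wald intervals for d and e (computed on the log scale)."""
        z = scipy.stats.norm.ppf(1 - alpha / 2)
        out = {}
        for name, value, se in (
            ("d", self.params.d, self.bse_log[0]),
            ("e", self.params.e, self.bse_log[1]),
        ):
            if np.isfinite(se):
                out[name] = (value * np.exp(-z * se), value * np.exp(z * se))
            else:
                out[name] = (np.nan, np.nan)
        return out

    def ancestral_ranges(self, force: bool = False):
        """Marginal ancestral range probabilities under the fitted rates."""
        from .ancestral import marginal_ancestral_ranges

        return marginal_ancestral_ranges(self, force=force)

    def node_summaries(self, threshold: float = 0.5) -> pd.DataFrame:
        return self.ancestral_ranges().node_table(threshold=threshold)

    def summary(self) -> str:
        spec = self.spec
        mode = {"distance": "distance-dependent", "uniform": "uniform",
                "minimal": "minimal (epsilon)"}[spec.mode]
        lines = [
            "Time-stratified DEC model fit",
            "=" * 46,
            f"Model:            {spec.id} ({mode} dispersal, "
            f"{'with' if spec.gaarlandia else 'without'} land bridge)",
            f"Tips / areas:     {self.model.tree.n_tips} / "
            f"{self.model.geography.n_areas}",
            f"Time slices:      {len(self.model.engine.slices)}",
            f"-ln L:            {self.neg_ln_L:.4f}",
            f"Dispersal d:      {self.params.d:.6g} per My"
            + (f"  (SE log d {self.bse_log[0]:.3g})" if np.isfinite(self.bse_log[0]) else ""),
            f"Extinction e:     {self.params.e:.6g} per My"
            + (f"  (SE log e {self.bse_log[1]:.3g})" if np.isfinite(self.bse_log[1]) else ""),
            f"Converged:        {self.converged}   (starts={self.n_starts}, "
            f"total iterations={self.n_iter})",
        ]
        if self.at_bound:
            lines.append("Note: a rate sits at the lower optimisation bound.")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<DECResults model={self.spec.id} -lnL={self.neg_ln_L:.3f} "
            f"d={self.params.d:.4g} e={self.params.e:.4g}>"
        )



def fit_dec(
    tree: Phylogeny,
    tip_ranges,
    spec: DispersalModelSpec | str,
    geography: Geography,
    max_range_size: int | None = None,
    **fit_kwargs,
) -> DECResults:
    """Functional wrapper: build a :class:`DECModel` and fit it."""
    return DECModel(tree, tip_ranges, geography, spec, max_range_size).fit(**fit_kwargs)


@dataclass
class ModelComparison:
    """Fits of several dispersal hypotheses on one dataset."""

    fits: dict[str, DECResults | None]
    errors: dict[str, str]

    @property
    def table(self) -> pd.DataFrame:
        rows = []
        for mid, fit in self.fits.items():
            if fit is None:
                rows.append(
                    {"Model": mid, "negLnL": np.nan, "dispersal": np.nan,
                     "extinction": np.nan, "converged": False}
                )
            else:
                rows.append(
                    {
                        "Model": mid,
                        "negLnL": fit.neg_ln_L,
                        "dispersal": fit.params.d,
                        "extinction": fit.params.e,
                        "converged": fit.converged,
                    }
                )
        return pd.DataFrame(rows)

    def delta_table(self) -> pd.DataFrame:
        """Pairwise differences in −ln L (row minus column)."""
        ids = list(self.fits)
        vals = {
            mid: (self.fits[mid].neg_ln_L if self.fits[mid] else np.nan)
            for mid in ids
        }
        return pd.DataFrame(
            [[vals[a] - vals[b] for b in ids] for a in ids], index=ids, columns=ids
        )

    def best(self) -> DECResults:
        ok = [f for f in self.fits.values() if f is not None]
        return min(ok, key=lambda f: f.neg_ln_L)

    def to_tsv(self, path=None) -> str:
        text = self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")
        return text

    def summary(self) -> str:
        tab = self.table
        out = ["Model comparison (−ln L; smaller is better)", "-" * 46]
        out.append(tab.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
        return "\n".join(out)


def compare_models(
    tree: Phylogeny,
    tip_ranges,
    geography: Geography,
    specs=("A", "B", "C", "D", "E", "F"),
    max_range_size: int | None = None,
    **fit_kwargs,
) -> ModelComparison:
    """Fit each hypothesis and tabulate −ln L / dispersal / extinction.

    Per-model failures are recorded and do not abort the remaining fits.
    """
    if len(specs) < 2:
        raise ValueError("compare_models needs at least two model specs")
    fits: dict[str, DECResults | None] = {}
    errors: dict[str, str] = {}
    for spec in specs:
        sid = spec if isinstance(spec, str) else spec.id
        try:
            fits[sid] = fit_dec(
                tree, tip_ranges, spec, geography, max_range_size, **fit_kwargs
            )
        except Exception as exc:  # noqa: BLE001 - per-row error contract
            logger.warning("model %s failed: %s", sid, exc)
            fits[sid] = None
            errors[sid] = str(exc)
    return ModelComparison(fits=fits, errors=errors)
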