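"""Two-population divergence models fitted to the joint SFS.

Four divergence histories are supported, all starting from an ancestral
population of size Nref that splits at ``t_split`` (backwards time, units of
2*Nref generations) into daughter populations of relative sizes nu1 and nu2:

* SI - strict isolation, no gene flow after the split;
* IM - isolation with continuous migration since the split;
* AM - ancient migration: gene flow only between ``t_am`` and ``t_split``;
* SC - secondary contact: gene flow only between the present and ``t_sc``.

Gene flow is scaled as M = 2*Nref*m (receiving-population convention).  Two
kinds of genomic heterogeneity can be layered on top of any model:

* heterogeneous migration ("2M"): a proportion P of loci exchange at the full
  rates (M12, M21) while 1-P are barrier loci with reduced effective rates
  (me12, me21);
* heterogeneous drift ("2N"): a proportion Q of loci experience linked
  selection, modelled as a Hill-Robertson rescaling of every deme size
  (including the ancestral deme) by a factor hrf in (0, 1].

The two processes are assumed independent, giving four locus categories with
product weights.  Exponential growth adds sizes-at-split nu1_0, nu2_0.

Expected spectra come from the branch-length Monte Carlo engine in
:mod:`expansionload.coalescent`; the composite likelihood is Poisson over
unmasked jSFS cells with the overall scale theta profiled out analytically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, gammaln, logit

from .coalescent import expected_branchlengths
from .sfs import JointSFS

__all__ = [
    "DemographicParams", "ModelSpec", "FitResult", "ModelSelectionTable",
    "UnitConversion", "expected_jsfs", "mixture_jsfs", "composite_ll",
    "fit_model", "select_model", "hierarchical_protocol", "simulate_dataset",
    "parametric_bootstrap", "convert_units", "invert_units",
    "DEFAULT_BOUNDS", "param_count", "values_from_params", "category_weights",
]

BASE_MODELS = ("SI", "IM", "AM", "SC")


@dataclass
class DemographicParams:
    """One divergence scenario in coalescent-scaled units."""

    model: str
    nu1: float = 1.0
    nu2: float = 1.0
    t_split: float = 1.0
    t_sc: float = 0.0
    t_am: float = 0.0
    M12: float = 0.0
    M21: float = 0.0
    me12: float = 0.0
    me21: float = 0.0
    P: float = 1.0
    Q: float = 0.0
    hrf: float = 1.0
    nu1_0: float | None = None
    nu2_0: float | None = None

    def validate(self) -> "DemographicParams":
        if self.model not in BASE_MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        for name in ("nu1", "nu2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("nu1_0", "nu2_0"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.t_split < 0:
            raise ValueError("t_split must be >= 0")
        if not (0 <= self.t_sc <= self.t_split):
            raise ValueError("need 0 <= t_sc <= t_split")
        if not (0 <= self.t_am <= self.t_split):
            raise ValueError("need 0 <= t_am <= t_split")
        if not (0 <= self.P <= 1 and 0 <= self.Q <= 1):
            raise ValueError("P and Q must lie in [0, 1]")
        if not (0 < self.hrf <= 1):
            raise ValueError("hrf must lie in (0, 1]")
        for name in ("M12", "M21", "me12", "me21"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.model == "SI" and (self.M12 or self.M21 or self.me12 or self.me21):
            raise ValueError("SI forbids migration")
        return self

    def migration_window(self) -> tuple[float, float]:
        if self.model == "IM":
            return 0.0, self.t_split
        if self.model == "AM":
            return self.t_am, self.t_split
        if self.model == "SC":
            return 0.0, self.t_sc
        return 0.0, 0.0


def expected_jsfs(params: DemographicParams, n1: int, n2: int, *,
                  barrier: bool = False, reduced_ne: bool = False,
                  n_genealogies: int = 10_000, seed: int = 0,
                  folded: bool = False) -> JointSFS:
    """Expected (unnormalized) jSFS for a single locus category.

    ``barrier`` selects the reduced effective migration rates (me12, me21);
    ``reduced_ne`` applies the Hill-Robertson size rescaling to every deme.
    """
    params.validate()
    scale = params.hrf if reduced_ne else 1.0
    m12, m21 = (params.me12, params.me21) if barrier else (params.M12, params.M21)
    mig_start, mig_stop = params.migration_window()
    nu1_0 = params.nu1_0 if params.nu1_0 is not None else params.nu1
    nu2_0 = params.nu2_0 if params.nu2_0 is not None else params.nu2
    bl = expected_branchlengths(
        n1, n2,
        nu1=params.nu1 * scale, nu2=params.nu2 * scale,
        nu1_0=nu1_0 * scale, nu2_0=nu2_0 * scale,
        t_split=params.t_split, nu_anc=scale,
        mig_start=mig_start, mig_stop=mig_stop, m12=m12, m21=m21,
        n_reps=n_genealogies, seed=seed)
    out = JointSFS(bl, folded=False)
    return out.fold() if folded else out


def category_weights(params: DemographicParams) -> dict[tuple[bool, bool], float]:
    """Product weights of the four (barrier, reduced_ne) locus categories."""
    P, Q = params.P, params.Q
    return {
        (False, False): P * (1 - Q),
        (True, False): (1 - P) * (1 - Q),
        (False, True): P * Q,
        (True, True): (1 - P) * Q,
    }


def mixture_jsfs(params: DemographicParams, n1: int, n2: int, *,
                 n_genealogies: int = 10_000, seed: int = 0,
                 folded: bool = False) -> JointSFS:
    """Expected jSFS under the four-category heterogeneity mixture.

    The same RNG seed is reused for every category, so nested-model
    identities (me = M, hrf = 1, P or Q degenerate) hold exactly at finite
    Monte Carlo size; reusing draws does not bias the weighted expectation.
    """
    weights = category_weights(params)
    acc = None
    for (barrier, reduced), w in weights.items():
        if w == 0.0:
            continue
        spec = expected_jsfs(params, n1, n2, barrier=barrier, reduced_ne=reduced,
                             n_genealogies=n_genealogies, seed=seed, folded=False)
        acc = w * spec.counts if acc is None else acc + w * spec.counts
    out = JointSFS(acc, folded=False)
    return out.fold() if folded else out


def composite_ll(obs: JointSFS, model: JointSFS) -> tuple[float, float]:
    """Poisson composite log-likelihood with analytically optimal scaling.

    theta_hat = sum(obs) / sum(model) over unmasked cells; returns
    (logL, theta_hat).
    """
    if obs.counts.shape != model.counts.shape:
        raise ValueError("obs and model jSFS shapes differ")
    if obs.folded != model.folded:
        raise ValueError("obs and model fold state differ")
    if not np.array_equal(obs.mask, model.mask):
        raise ValueError("obs and model masks differ")
    o = obs.counts[~obs.mask]
    m = model.counts[~model.mask].copy()
    bad = (m <= 0) & (o > 0)
    if bad.any():
        warnings.warn(f"flooring {bad.sum()} zero model cells with observed data")
        floor = m[m > 0].min() * 1e-6 if (m > 0).any() else 1e-12
        m[m <= 0] = floor
    theta = o.sum() / m.sum()
    lam = theta * m
    keep = lam > 0
    ll = float(np.sum(o[keep] * np.log(lam[keep]) - lam[keep] - gammaln(o[keep] + 1))
               - lam[~keep].sum())
    return ll, float(theta)


# ---------------------------------------------------------------------------
# model variants and fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    base: str
    hetero_m: bool = False
    hetero_n: bool = False
    growth: bool = False

    @property
    def name(self) -> str:
        s = self.base
        if self.hetero_n:
            s += "2N"
        if self.hetero_m:
            s += "2M"
        if self.growth:
            s += "+g"
        return s

    @classmethod
    def parse(cls, name: str) -> "ModelSpec":
        growth = name.endswith("+g")
        if growth:
            name = name[:-2]
        base = name[:2]
        if base not in BASE_MODELS:
            raise ValueError(f"unknown model variant {name!r}")
        rest = name[2:]
        hetero_n = "2N" in rest
        hetero_m = "2M" in rest
        if rest.replace("2N", "").replace("2M", ""):
            raise ValueError(f"unknown model variant suffix in {name!r}")
        return cls(base, hetero_m, hetero_n, growth)

    def free_params(self) -> list[str]:
        names = ["nu1", "nu2", "t_split"]
        if self.base == "SC":
            names.append("f_sc")
        elif self.base == "AM":
            names.append("f_am")
        if self.base != "SI":
            names += ["M12", "M21"]
            if self.hetero_m:
                names += ["P", "me12", "me21"]
        if self.hetero_n:
            names += ["Q", "hrf"]
        if self.growth:
            names += ["nu1_0", "nu2_0"]
        return names


def param_count(spec: ModelSpec | str) -> int:
    """Number of free parameters (k in AIC = 2k - 2 logL); theta is profiled."""
    if isinstance(spec, str):
        spec = ModelSpec.parse(spec)
    return len(spec.free_params())


# (lower, upper); positive parameters are optimized in log space, fraction
# parameters through a logit transform of (v - lo) / (hi - lo).
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "nu1": (0.01, 100.0), "nu2": (0.01, 100.0),
    "nu1_0": (0.01, 100.0), "nu2_0": (0.01, 100.0),
    "t_split": (0.02, 20.0),
    "f_sc": (0.01, 0.99), "f_am": (0.01, 0.99),
    "M12": (1e-3, 50.0), "M21": (1e-3, 50.0),
    "me12": (1e-3, 50.0), "me21": (1e-3, 50.0),
    "P": (0.01, 0.99), "Q": (0.01, 0.99), "hrf": (0.01, 0.99),
}

_FRACTION_PARAMS = {"f_sc", "f_am", "P", "Q", "hrf"}


def _to_internal(name: str, v: float, bounds) -> float:
    lo, hi = bounds[name]
    v = min(max(v, lo), hi)
    if name in _FRACTION_PARAMS:
        x = (v - lo) / (hi - lo)
        x = min(max(x, 1e-9), 1 - 1e-9)
        return float(logit(x))
    return float(np.log(v))


def _from_internal(name: str, x: float, bounds) -> float:
    lo, hi = bounds[name]
    if name in _FRACTION_PARAMS:
        return float(lo + (hi - lo) * expit(x))
    return float(min(max(np.exp(x), lo), hi))


def _params_from_values(spec: ModelSpec, values: dict[str, float]) -> DemographicParams:
    p = DemographicParams(model=spec.base,
                          nu1=values["nu1"], nu2=values["nu2"],
                          t_split=values["t_split"])
    if spec.base == "SC":
        p.t_sc = values["f_sc"] * p.t_split
    elif spec.base == "AM":
        p.t_am = values["f_am"] * p.t_split
    if spec.base != "SI":
        p.M12, p.M21 = values["M12"], values["M21"]
        if spec.hetero_m:
            p.P = values["P"]
            p.me12, p.me21 = values["me12"], values["me21"]
        else:
            p.P = 1.0
    if spec.hetero_n:
        p.Q, p.hrf = values["Q"], values["hrf"]
    if spec.growth:
        p.nu1_0, p.nu2_0 = values["nu1_0"], values["nu2_0"]
    return p.validate()


def values_from_params(spec: ModelSpec, p: DemographicParams) -> dict[str, float]:
    """Free-parameter dictionary for ``spec`` extracted from a params object."""
    values: dict[str, float] = {"nu1": p.nu1, "nu2": p.nu2, "t_split": p.t_split}
    if spec.base == "SC":
        values["f_sc"] = p.t_sc / p.t_split if p.t_split > 0 else 0.5
    elif spec.base == "AM":
        values["f_am"] = p.t_am / p.t_split if p.t_split > 0 else 0.5
    if spec.base != "SI":
        values["M12"], values["M21"] = p.M12, p.M21
        if spec.hetero_m:
            values["P"] = p.P
            values["me12"], values["me21"] = p.me12, p.me21
    if spec.hetero_n:
        values["Q"], values["hrf"] = p.Q, p.hrf
    if spec.growth:
        values["nu1_0"] = p.nu1_0 if p.nu1_0 is not None else p.nu1
        values["nu2_0"] = p.nu2_0 if p.nu2_0 is not None else p.nu2
    return values


@dataclass
class FitResult:
    spec: ModelSpec
    params: DemographicParams
    ll: float
    theta: float
    k: int
    aic: float
    best_start: int
    seed: int
    converged: bool
    replicates: list = field(default_factory=list)  # (ll, values dict) per start

    @property
    def name(self) -> str:
        return self.spec.name


#: neutral mid-range starting values for the local searches
_CENTER_START = {"nu1": 1.0, "nu2": 1.0, "nu1_0": 1.0, "nu2_0": 1.0,
                 "t_split": 1.0, "f_sc": 0.3, "f_am": 0.3,
                 "M12": 1.0, "M21": 1.0, "me12": 0.05, "me21": 0.05,
                 "P": 0.5, "Q": 0.5, "hrf": 0.3}


def fit_model(obs: JointSFS, variant: str | ModelSpec, *, n_starts: int = 20,
              seed: int = 0, n_genealogies: int = 2000, maxiter: int | None = None,
              bounds: dict | None = None, init: dict | None = None,
              step: float = 0.7, init_jitter: float = 0.0,
              refine: bool = True) -> FitResult:
    """Maximize the composite likelihood over a model variant's free parameters.

    Runs ``n_starts`` replicate Nelder-Mead searches on the transformed
    parameters (log for positive parameters, logit for proportions).  The
    first start is the warm start ``init`` when given, the next the neutral
    mid-range point, the rest log-uniform random draws within bounds.  Each
    replicate runs two Nelder-Mead rounds: a wide round whose initial
    simplex spans ``step`` in transformed space (about a factor of two per
    parameter - the scipy default simplex is far too small to traverse this
    rugged surface), then a refinement restart with a smaller simplex at the
    round-1 solution.  The best replicate is returned; all are logged in
    ``replicates``.

    The Monte Carlo seed of the expected-SFS engine is fixed for the whole
    fit, so the objective is deterministic and comparable across starts.
    """
    spec = ModelSpec.parse(variant) if isinstance(variant, str) else variant
    names = spec.free_params()
    bnds = dict(DEFAULT_BOUNDS)
    if bounds:
        bnds.update(bounds)
    rng = np.random.default_rng(seed)
    eval_seed = int(rng.integers(2**31))
    n1, n2 = obs.n1, obs.n2
    if maxiter is None:
        maxiter = 150 * len(names)

    def objective(x):
        values = {nm: _from_internal(nm, xi, bnds) for nm, xi in zip(names, x)}
        try:
            p = _params_from_values(spec, values)
        except ValueError:
            return 1e12
        model = mixture_jsfs(p, n1, n2, n_genealogies=n_genealogies,
                             seed=eval_seed, folded=obs.folded)
        ll, _ = composite_ll(obs, model)
        return -ll

    def local_search(x0, width, budget):
        d = len(x0)
        simplex = np.vstack([x0] + [x0 + width * np.eye(d)[i] for i in range(d)])
        return minimize(objective, x0, method="Nelder-Mead",
                        options={"maxiter": budget, "fatol": 1e-2, "xatol": 1e-3,
                                 "initial_simplex": simplex, "adaptive": True})

    def draw_start():
        values = {}
        for nm in names:
            lo, hi = bnds[nm]
            if nm in _FRACTION_PARAMS:
                values[nm] = lo + (hi - lo) * rng.uniform(0.05, 0.95)
            else:
                values[nm] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        return values

    starts = []
    if init is not None:
        warm = {nm: init.get(nm, _CENTER_START[nm]) for nm in names}
        if init_jitter > 0:
            # over-disperse warm starts so searches do not anchor inside flat
            # (weakly identified) regions of the likelihood surface
            x = np.array([_to_internal(nm, warm[nm], bnds) for nm in names])
            x = x + rng.normal(0.0, init_jitter, size=len(x))
            warm = {nm: _from_internal(nm, xi, bnds) for nm, xi in zip(names, x)}
        starts.append(warm)
    starts.append({nm: _CENTER_START[nm] for nm in names})
    while len(starts) < n_starts:
        starts.append(draw_start())
    starts = starts[:max(n_starts, 1)]

    best = None
    replicates = []
    any_converged = False
    for start, values0 in enumerate(starts):
        x0 = np.array([_to_internal(nm, values0[nm], bnds) for nm in names])
        res = local_search(x0, step, maxiter)
        if refine:
            res2 = local_search(res.x, step / 2.5, maxiter // 2)
            if res2.fun < res.fun:
                res = res2
        values = {nm: _from_internal(nm, xi, bnds) for nm, xi in zip(names, res.x)}
        ll = -res.fun
        replicates.append((ll, values))
        any_converged = any_converged or bool(res.success)
        if best is None or ll > best[0]:
            best = (ll, values, start)
    if best is None or not np.isfinite(best[0]):
        raise RuntimeError("all optimization starts failed")
    ll, values, start = best
    params = _params_from_values(spec, values)
    model = mixture_jsfs(params, n1, n2, n_genealogies=n_genealogies,
                         seed=eval_seed, folded=obs.folded)
    _, theta = composite_ll(obs, model)
    k = len(names)
    return FitResult(spec=spec, params=params, ll=ll, theta=theta, k=k,
                     aic=2 * k - 2 * ll, best_start=start, seed=seed,
                     converged=any_converged, replicates=replicates)


@dataclass
class ModelSelectionTable:
    table: pd.DataFrame  # model, k, logL, AIC, dAIC, weight (sorted by AIC)
    ambiguous: bool

    @property
    def best(self) -> str:
        return str(self.table.iloc[0]["model"])


def select_model(fits: dict[str, FitResult] | list[FitResult]) -> ModelSelectionTable:
    """Rank fitted variants by AIC; flag ambiguity when runner-up dAIC < 10."""
    if isinstance(fits, dict):
        fits = list(fits.values())
    if len(fits) < 2:
        raise ValueError("model selection needs at least two fitted models")
    rows = [{"model": f.name, "k": f.k, "logL": f.ll, "AIC": f.aic} for f in fits]
    df = pd.DataFrame(rows).sort_values("AIC", kind="stable").reset_index(drop=True)
    df["dAIC"] = df["AIC"] - df["AIC"].iloc[0]
    rel = np.exp(-df["dAIC"] / 2)
    df["weight"] = rel / rel.sum()
    ambiguous = bool(df["dAIC"].iloc[1] < 10)
    return ModelSelectionTable(table=df, ambiguous=ambiguous)


def hierarchical_protocol(obs: JointSFS, *, bases=BASE_MODELS,
                          hetero=((False, False), (False, True), (True, False), (True, True)),
                          n_starts: int = 20, seed: int = 0,
                          n_genealogies: int = 2000, maxiter: int | None = None) -> dict:
    """Two-stage model selection.

    Stage 1 fits every constant-size variant (bases x heterogeneity flags);
    stage 2 adds the two exponential-growth parameters to the stage-1 winner
    (and to any variant within dAIC < 10 of it), warm-started at the stage-1
    solution.  Final parameter estimates come from stage 2.
    """
    rng = np.random.default_rng(seed)
    stage1: dict[str, FitResult] = {}
    for base in bases:
        for hm, hn in hetero:
            spec = ModelSpec(base, hetero_m=hm, hetero_n=hn, growth=False)
            stage1[spec.name] = fit_model(
                obs, spec, n_starts=n_starts, seed=int(rng.integers(2**31)),
                n_genealogies=n_genealogies, maxiter=maxiter)
    sel1 = select_model(stage1)
    winners = sel1.table[sel1.table["dAIC"] < 10]["model"].tolist()
    stage2: dict[str, FitResult] = {}
    for name in winners:
        parent = stage1[name]
        spec = replace(parent.spec, growth=True)
        init = values_from_params(spec, parent.params)
        stage2[spec.name] = fit_model(
            obs, spec, n_starts=max(1, n_starts // 2), seed=int(rng.integers(2**31)),
            n_genealogies=n_genealogies, maxiter=maxiter, init=init)
    candidates = list(stage2.values())
    final = max(candidates, key=lambda f: -f.aic) if candidates else stage1[sel1.best]
    sel2 = select_model(candidates) if len(candidates) > 1 else None
    return {"stage1": stage1, "selection1": sel1,
            "stage2": stage2, "selection2": sel2, "final": final}


def simulate_dataset(params: DemographicParams, n1: int, n2: int, *,
                     n_sites: int, n_loci: int = 1000, n_genealogies: int = 5000,
                     seed: int = 0, folded: bool = False,
                     return_labels: bool = False):
    """Draw an observed jSFS from a scenario (multinomial around the mixture).

    Loci are assigned to the four heterogeneity categories multinomially with
    the product weights; n_sites segregating sites are then drawn from the
    mixture of category spectra weighted by realized category fractions.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    weights = category_weights(params)
    cats = list(weights)
    n_per_cat = rng.multinomial(n_loci, [weights[c] for c in cats])
    acc = None
    for (barrier, reduced), n_cat in zip(cats, n_per_cat):
        if n_cat == 0:
            continue
        spec = expected_jsfs(params, n1, n2, barrier=barrier, reduced_ne=reduced,
                             n_genealogies=n_genealogies,
                             seed=int(rng.integers(2**31)), folded=False)
        acc = (n_cat / n_loci) * spec.counts if acc is None else \
            acc + (n_cat / n_loci) * spec.counts
    expected = JointSFS(acc, folded=False)
    if folded:
        expected = expected.fold()
    p = expected.counts[~expected.mask]
    p = p / p.sum()
    draw = rng.multinomial(n_sites, p)
    counts = np.zeros_like(expected.counts)
    counts[~expected.mask] = draw
    obs = JointSFS(counts, folded=folded)
    if return_labels:
        labels = np.repeat(
            [f"{'barrier' if b else 'full-m'}/{'reduced-Ne' if r else 'full-Ne'}"
             for b, r in cats], n_per_cat)
        rng.shuffle(labels)
        return obs, labels
    return obs


def parametric_bootstrap(fit: FitResult, obs: JointSFS, *, reps: int = 100,
                         seed: int = 0, n_loci: int = 1000,
                         n_starts: int = 1, n_genealogies: int = 2000,
                         maxiter: int | None = None,
                         init_jitter: float = 0.7) -> dict:
    """Percentile CIs from refits of data resimulated at the fitted parameters.

    Each replicate resimulates the four category datasets at the point
    estimates (category locus counts multinomial in the product weights),
    sums them into one jSFS with the same number of sites as the data, and
    refits the same model variant warm-started at the point estimates.  Refits
    draw fresh Monte Carlo seeds, so the intervals include the expected-SFS
    engine noise.  Failed replicates are dropped and counted.
    """
    rng = np.random.default_rng(seed)
    n_sites = int(round(obs.total()))
    init = values_from_params(fit.spec, fit.params)
    rows = []
    n_failed = 0
    for _ in range(reps):
        boot = simulate_dataset(fit.params, obs.n1, obs.n2, n_sites=n_sites,
                                n_loci=n_loci, n_genealogies=n_genealogies,
                                seed=int(rng.integers(2**31)), folded=obs.folded)
        try:
            refit = fit_model(boot, fit.spec, n_starts=n_starts,
                              seed=int(rng.integers(2**31)),
                              n_genealogies=n_genealogies, maxiter=maxiter,
                              init=init, step=0.7, init_jitter=init_jitter,
                              refine=False)
        except RuntimeError:
            n_failed += 1
            continue
        rows.append(values_from_params(fit.spec, refit.params))
    if not rows:
        raise RuntimeError("every bootstrap replicate failed")
    est = pd.DataFrame(rows)
    ci = {name: (float(np.percentile(est[name], 2.5)),
                 float(np.percentile(est[name], 97.5)))
          for name in est.columns}
    return {"ci": ci, "estimates": est, "n_failed": n_failed}


# ---------------------------------------------------------------------------
# unit conversion
# ---------------------------------------------------------------------------

@dataclass
class UnitConversion:
    """Scaling from model units to demographic units.

    mu: mutation rate per bp per generation; L: effective sequence length in
    bp; g: generation time in years; theta: fitted composite-likelihood scale.
    Nref = theta / (4 * mu * L).
    """

    theta: float
    L: float
    mu: float = 8e-9
    g: float = 3.0

    def __post_init__(self):
        for name in ("theta", "L", "mu", "g"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def nref(self) -> float:
        return self.theta / (4 * self.mu * self.L)


def convert_units(params: DemographicParams, uc: UnitConversion) -> dict:
    """Sizes in diploid individuals, times in years, migration per generation."""
    nref = uc.nref
    out = {
        "Nref": nref,
        "Nanc": nref,
        "N1": params.nu1 * nref,
        "N2": params.nu2 * nref,
        "Tsplit_years": params.t_split * 2 * nref * uc.g,
        "Tsc_years": params.t_sc * 2 * nref * uc.g,
        "Tam_years": params.t_am * 2 * nref * uc.g,
        "m12_per_gen": params.M12 / (2 * nref),
        "m21_per_gen": params.M21 / (2 * nref),
        "me12_per_gen": params.me12 / (2 * nref),
        "me21_per_gen": params.me21 / (2 * nref),
    }
    if params.nu1_0 is not None:
        out["N1_at_split"] = params.nu1_0 * nref
    if params.nu2_0 is not None:
        out["N2_at_split"] = params.nu2_0 * nref
    return out


def invert_units(report: dict, uc: UnitConversion, model: str = "IM") -> DemographicParams:
    """Inverse of :func:`convert_units` (round-trip identity up to float error)."""
    nref = uc.nref
    return DemographicParams(
        model=model,
        nu1=report["N1"] / nref,
        nu2=report["N2"] / nref,
        t_split=report["Tsplit_years"] / (2 * nref * uc.g),
        t_sc=report["Tsc_years"] / (2 * nref * uc.g),
        t_am=report["Tam_years"] / (2 * nref * uc.g),
        M12=report["m12_per_gen"] * 2 * nref,
        M21=report["m21_per_gen"] * 2 * nref,
        me12=report["me12_per_gen"] * 2 * nref,
        me21=report["me21_per_gen"] * 2 * nref,
    )
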