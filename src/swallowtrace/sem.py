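"""Confirmatory path analysis (piecewise SEM) of winter carry-over effects.

The causal hypothesis: winter habitat quality (NDVI), age and their
interaction set breeding date, breeding date drives clutch size (females)
and fledgling numbers, and tail ornament length shifts the whole cascade.
Body mass is tied to each reproductive variable by correlated errors
(bidirectional arcs), because measurement timing leaves the causal direction
unknown. The DAG is fitted piecewise as one Gaussian linear mixed model per
endogenous variable with crossed random intercepts for ring, colony and
year; goodness of fit of the whole network is Shipley's d-separation test
combined by Fisher's C = −2 Σ ln p ~ χ²(2k).

All path coefficients are standardized (z-scored variables, with the
age×NDVI interaction formed as the product of the raw variables and then
itself z-scored); raw-scale coefficients are kept alongside.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .lmm import MixedLMResult, fit_crossed_lmm

RANDOM_FACTORS = ["ring_id", "colony_id", "year"]
INTERACTION = "age_ndvi"


# ---------------------------------------------------------------------------
# model definition


@dataclass
class PathModel:
    """A DAG over observed variables plus correlated-error pairs."""

    edges: list[tuple[str, str]]
    correlated: list[frozenset] = field(default_factory=list)
    random_factors: list[str] = field(default_factory=lambda: list(RANDOM_FACTORS))
    sex: str = ""

    def __post_init__(self) -> None:
        self.correlated = [frozenset(p) for p in self.correlated]
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("path model must be acyclic")
        directed = {frozenset(e) for e in self.edges}
        clash = [tuple(p) for p in self.correlated if p in directed]
        if clash:
            raise ValueError(f"correlated-error pairs duplicate directed edges: {clash}")

    def graph(self) -> nx.DiGraph:
        return nx.DiGraph(self.edges)

    @property
    def variables(self) -> list[str]:
        g = self.graph()
        extra = sorted({v for pair in self.correlated for v in pair} - set(g.nodes))
        return list(nx.topological_sort(g)) + extra

    @property
    def endogenous(self) -> list[str]:
        g = self.graph()
        return [v for v in nx.topological_sort(g) if g.in_degree(v) > 0]

    def parents(self, var: str) -> list[str]:
        g = self.graph()
        return sorted(g.predecessors(var)) if var in g else []

    def to_json(self, path) -> None:
        payload = dict(
            edges=self.edges,
            correlated=[sorted(p) for p in self.correlated],
            random_factors=self.random_factors,
            sex=self.sex,
        )
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "PathModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            edges=[tuple(e) for e in d["edges"]],
            correlated=[frozenset(p) for p in d.get("correlated", [])],
            random_factors=d.get("random_factors", list(RANDOM_FACTORS)),
            sex=d.get("sex", ""),
        )


def female_model() -> PathModel:
    """NDVI/age/interaction/tail → breeding date → clutch → fledglings,
    with body-mass correlated errors on every reproductive variable."""
    edges = [
        ("winter_ndvi", "breeding_date"),
        ("age", "breeding_date"),
        (INTERACTION, "breeding_date"),
        ("tail_length", "breeding_date"),
        ("breeding_date", "clutch_size"),
        ("age", "clutch_size"),
        ("tail_length", "clutch_size"),
        ("clutch_size", "fledglings"),
        ("age", "fledglings"),
        ("tail_length", "fledglings"),
    ]
    correlated = [
        frozenset({"body_mass", "breeding_date"}),
        frozenset({"body_mass", "clutch_size"}),
        frozenset({"body_mass", "fledglings"}),
    ]
    return PathModel(edges=edges, correlated=correlated, sex="female")


def male_model() -> PathModel:
    """Female model without the clutch node (clutch size is set by the
    female, so it is dropped from the male causal network)."""
    edges = [
        ("winter_ndvi", "breeding_date"),
        ("age", "breeding_date"),
        (INTERACTION, "breeding_date"),
        ("tail_length", "breeding_date"),
        ("breeding_date", "fledglings"),
        ("age", "fledglings"),
        ("tail_length", "fledglings"),
    ]
    correlated = [
        frozenset({"body_mass", "breeding_date"}),
        frozenset({"body_mass", "fledglings"}),
    ]
    return PathModel(edges=edges, correlated=correlated, sex="male")


# ---------------------------------------------------------------------------
# standardization


@dataclass
class Standardization:
    """Means and SDs (n−1 denominator) used to z-score the analysis set."""

    means: dict
    sds: dict

    def to_z(self, var: str, raw):
        return (raw - self.means[var]) / self.sds[var]

    def to_raw(self, var: str, z):
        return z * self.sds[var] + self.means[var]


def add_interaction(table: pd.DataFrame) -> pd.DataFrame:
    """Attach the raw age×NDVI product column."""
    out = table.copy()
    out[INTERACTION] = out["age"].astype(float) * out["winter_ndvi"].astype(float)
    return out


def standardize(table: pd.DataFrame, variables: list[str]):
    """Z-score ``variables`` on the listwise-complete analysis set.

    The interaction column, when requested, is the product of raw age and
    raw NDVI and is itself z-scored. Returns (standardized table including
    the untouched non-model columns, Standardization).
    """
    tab = add_interaction(table) if INTERACTION in variables and INTERACTION not in table else table.copy()
    tab = tab.dropna(subset=variables)
    means, sds = {}, {}
    out = tab.copy()
    for v in variables:
        x = tab[v].astype(float)
        mu, sd = float(x.mean()), float(x.std(ddof=1))
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"variable '{v}' has zero variance; cannot standardize")
        means[v], sds[v] = mu, sd
        out[v] = (x - mu) / sd
    return out, Standardization(means=means, sds=sds)


# ---------------------------------------------------------------------------
# sub-model fits


@dataclass
class SubmodelFit:
    """One endogenous variable's mixed-model fit, standardized scale."""

    response: str
    predictors: list[str]
    estimates: pd.Series  # standardized path coefficients
    ses: pd.Series
    pvalues: pd.Series
    raw_estimates: pd.Series  # back-transformed to raw units
    re_var: dict
    resid_var: float
    conditional_r2: float
    n: int
    result: MixedLMResult = field(repr=False, default=None)

    def coef(self, predictor: str) -> float:
        return float(self.estimates[predictor])

    def p(self, predictor: str) -> float:
        return float(self.pvalues[predictor])

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            dict(
                response=self.response,
                predictor=self.predictors,
                estimate=[self.estimates[p] for p in self.predictors],
                se=[self.ses[p] for p in self.predictors],
                p=[self.pvalues[p] for p in self.predictors],
                conditional_r2=self.conditional_r2,
            )
        )


def fit_submodel(
    model: PathModel, response: str, zdata: pd.DataFrame, scaler: Standardization
) -> SubmodelFit:
    """Fit one endogenous variable on its DAG parents (standardized LMM, ML,
    crossed random intercepts; fails loudly if a factor column is absent)."""
    predictors = model.parents(response)
    if not predictors:
        raise ValueError(f"'{response}' has no parents in the model")
    for f in model.random_factors:
        if f not in zdata.columns:
            raise ValueError(f"random factor '{f}' missing from data")
    res = fit_crossed_lmm(zdata, response, predictors, model.random_factors)
    raw = pd.Series(
        {
            p: res.params[p] * scaler.sds[response] / scaler.sds[p]
            for p in predictors
        }
    )
    return SubmodelFit(
        response=response,
        predictors=predictors,
        estimates=res.params[predictors],
        ses=res.bse[predictors],
        pvalues=res.pvalues[predictors],
        raw_estimates=raw,
        re_var=res.re_var,
        resid_var=res.resid_var,
        conditional_r2=res.conditional_r2,
        n=res.n,
        result=res,
    )


# ---------------------------------------------------------------------------
# d-separation


@dataclass
class IndependenceClaim:
    x: str  # topologically earlier
    y: str  # later; regressed on x
    conditioning: list[str]
    pvalue: float = np.nan


@dataclass
class DSeparationResult:
    claims: list[IndependenceClaim]
    fisher_c: float
    df: int
    pvalue: float

    def to_json(self, path) -> None:
        payload = dict(
            claims=[asdict(c) for c in self.claims],
            fisher_c=self.fisher_c,
            df=self.df,
            pvalue=self.pvalue,
        )
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def basis_set(model: PathModel) -> list[IndependenceClaim]:
    """Shipley's basis set: one claim per non-adjacent variable pair.

    Pairs joined by a directed edge or a correlated-error arc count as
    adjacent; exogenous–exogenous pairs are excluded. The topologically
    later variable is regressed on the earlier conditioning on the union of
    both variables' parents.
    """
    g = model.graph()
    order = {v: i for i, v in enumerate(nx.topological_sort(g))}
    exog = {v for v in g.nodes if g.in_degree(v) == 0}
    claims = []
    for a, b in itertools.combinations(sorted(g.nodes, key=order.get), 2):
        if g.has_edge(a, b) or g.has_edge(b, a):
            continue
        if frozenset({a, b}) in model.correlated:
            continue
        if a in exog and b in exog:
            continue
        x, y = (a, b) if order[a] <= order[b] else (b, a)
        cond = sorted((set(g.predecessors(x)) | set(g.predecessors(y))) - {x, y})
        claims.append(IndependenceClaim(x=x, y=y, conditioning=cond))
    return claims


def chi_square_upper_tail(C: float, df: int) -> float:
    """Upper tail of the chi-square distribution (Fisher's C reference)."""
    if C < 0:
        raise ValueError("C must be >= 0")
    if df < 1 or int(df) != df:
        raise ValueError("df must be a positive integer")
    return float(stats.chi2.sf(C, df))


def dsep_test(model: PathModel, zdata: pd.DataFrame) -> DSeparationResult:
    """Test every basis-set claim with a mixed model of the same random
    structure; combine with Fisher's C = −2 Σ ln p ~ χ²(2k)."""
    claims = basis_set(model)
    tested = []
    for cl in claims:
        res = fit_crossed_lmm(
            zdata, cl.y, cl.conditioning + [cl.x], model.random_factors
        )
        p = float(res.pvalues[cl.x])
        if p <= 0.0:
            warnings.warn("claim p-value underflowed; floored at 1e-300", stacklevel=2)
            p = 1e-300
        tested.append(
            IndependenceClaim(x=cl.x, y=cl.y, conditioning=cl.conditioning, pvalue=p)
        )
    C = -2.0 * sum(np.log([c.pvalue for c in tested])) if tested else 0.0
    df = 2 * len(tested)
    p = chi_square_upper_tail(C, df) if df else 1.0
    return DSeparationResult(claims=tested, fisher_c=float(C), df=df, pvalue=p)


# ---------------------------------------------------------------------------
# whole-analysis driver


@dataclass
class PathAnalysis:
    """All sub-model fits plus the d-separation test for one sex."""

    model: PathModel
    submodels: dict
    dsep: DSeparationResult
    scaler: Standardization
    zdata: pd.DataFrame = field(repr=False, default=None)

    def table(self) -> pd.DataFrame:
        """Stacked per-path summary (standardized estimates, SE, p, R²)."""
        return pd.concat(
            [self.submodels[r].table() for r in self.model.endogenous],
            ignore_index=True,
        )


def fit_path_model(model: PathModel, data: pd.DataFrame) -> PathAnalysis:
    """Standardize, fit every endogenous sub-model, run the d-sep test."""
    variables = [v for v in model.variables]
    zdata, scaler = standardize(data, variables)
    submodels = {r: fit_submodel(model, r, zdata, scaler) for r in model.endogenous}
    dsep = dsep_test(model, zdata)
    return PathAnalysis(model=model, submodels=submodels, dsep=dsep, scaler=scaler, zdata=zdata)


# ---------------------------------------------------------------------------
# indirect effects, correlated errors, prediction surfaces


@dataclass
class IndirectEffect:
    chain: list[tuple[str, str]]
    value: float
    component_coefficients: list[float]
    component_pvalues: list[float]
    all_significant: bool  # every component path significant at alpha


def indirect_effect(
    analysis: PathAnalysis, chain: list[tuple[str, str]], alpha: float = 0.05
) -> IndirectEffect:
    """Product of standardized path coefficients along a directed chain.

    The effect is conventionally reported only when every component path is
    itself significant; ``all_significant`` carries that gate.
    """
    coefs, ps = [], []
    for src, dst in chain:
        fit = analysis.submodels.get(dst)
        if fit is None or src not in fit.predictors:
            raise ValueError(f"edge {src}→{dst} not present in the fitted model")
        coefs.append(fit.coef(src))
        ps.append(fit.p(src))
    value = float(np.prod(coefs))
    return IndirectEffect(
        chain=list(chain),
        value=value,
        component_coefficients=coefs,
        component_pvalues=ps,
        all_significant=bool(all(p < alpha for p in ps)),
    )


def correlated_error(
    analysis: PathAnalysis, pair: tuple[str, str]
) -> tuple[float, float]:
    """Residual Pearson correlation for a bidirectional (correlated-error) arc.

    Endogenous variables contribute their mixed-model conditional residuals;
    an exogenous variable (body mass) is residualized by OLS on the model's
    exogenous covariates. Returns (r, two-sided t p-value).
    """
    res = []
    g = analysis.model.graph()
    exog = [v for v in analysis.model.variables if v in g.nodes and g.in_degree(v) == 0]
    for var in pair:
        if var in analysis.submodels:
            res.append(np.asarray(analysis.submodels[var].result.resid_conditional))
        else:
            y = analysis.zdata[var].to_numpy(dtype=float)
            X = np.column_stack(
                [np.ones(len(y))]
                + [analysis.zdata[e].to_numpy(dtype=float) for e in exog if e != var]
            )
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            res.append(y - X @ beta)
    a, b = res
    n = len(a)
    if n < 4:
        raise ValueError("need at least 4 residual pairs")
    r = float(np.corrcoef(a, b)[0, 1])
    t = r * np.sqrt((n - 2) / max(1 - r**2, 1e-300))
    p = float(2 * stats.t.sf(abs(t), df=n - 2))
    return r, p


def predict_surface(
    analysis: PathAnalysis,
    response: str,
    age_grid,
    ndvi_grid,
    fixed: dict | None = None,
) -> pd.DataFrame:
    """Fixed-effects-only predictions of ``response`` over an (age, NDVI)
    grid, in raw units, propagating predictions through the DAG.

    Exogenous covariates other than age/NDVI are held at ``fixed`` values
    (default: their analysis-set means). Grid points outside the observed
    covariate range are flagged in the ``extrapolated`` column, not refused.
    """
    fixed = fixed or {}
    scaler = analysis.scaler
    g = analysis.model.graph()
    ages = np.asarray(age_grid, dtype=float)
    ndvis = np.asarray(ndvi_grid, dtype=float)
    A, N = np.meshgrid(ages, ndvis, indexing="ij")
    values: dict[str, np.ndarray] = {
        "age": A,
        "winter_ndvi": N,
        INTERACTION: A * N,
    }
    for v in analysis.model.variables:
        if v in values or v in analysis.model.endogenous:
            continue
        values[v] = np.full_like(A, float(fixed.get(v, scaler.means.get(v, 0.0))))
    for resp in analysis.model.endogenous:  # topological order
        fit = analysis.submodels[resp]
        z = np.zeros_like(A)
        for pred in fit.predictors:
            z = z + fit.coef(pred) * scaler.to_z(pred, values[pred])
        values[resp] = scaler.to_raw(resp, z)
        if resp == response:
            break
    if response not in values:
        raise ValueError(f"'{response}' is not an endogenous variable of the model")
    # covariate-hull flag from the raw analysis set
    age_raw = scaler.to_raw("age", analysis.zdata["age"].to_numpy())
    ndvi_raw = scaler.to_raw("winter_ndvi", analysis.zdata["winter_ndvi"].to_numpy())
    extrap = (
        (A < age_raw.min()) | (A > age_raw.max()) | (N < ndvi_raw.min()) | (N > ndvi_raw.max())
    )
    if extrap.any():
        warnings.warn("prediction grid extends beyond the data's covariate hull", stacklevel=2)
    return pd.DataFrame(
        dict(
            age=A.ravel(),
            winter_ndvi=N.ravel(),
            predicted=values[response].ravel(),
            extrapolated=extrap.ravel(),
        )
    )
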