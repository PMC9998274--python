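"""Piecewise structural equation modelling of the island x site-class data.

The hypothesised causal structure links three island attributes — decreased
area DA = -ln(area), proximity to edge PE (interior 0, edge 1) and distance
to mainland DM = ln(distance) — to four community responses (FR floral
resources, PL plant richness, AB pollinator abundance, PO pollinator
richness) and four network-architecture responses (RC relative connectance,
NE nestedness, MO modularity, RO robustness).  Each endogenous variable gets
its own mixed model (gaussian LMM for FR and the network metrics, Poisson
GLMM for the richness/abundance counts), always with a random intercept for
island identity; all fits are ML so AICs are comparable.

Global fit is Shipley's d-separation test: every non-adjacent variable pair
not covered by a correlated-error arc yields an independence claim, the
claims' p-values combine into Fisher's C = -2 sum(ln p) ~ chi2(2k), and the
SEM-level AIC is C + 2K with K the total parameter count.  Model selection
removes whichever directed path most lowers that AIC until no removal helps.
Direct/indirect/total standardized effects come from path tracing, with
cluster-bootstrap (islands resampled) percentile intervals.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .io import IslandAttributes
from .mixed import GAUSSIAN, POISSON, FitError, MixedFit, fit_mixed
from .networks import CommunityMetrics
from .metrics import NetworkMetrics

EXOGENOUS = ("DA", "PE", "DM")
ENDOGENOUS = ("FR", "PL", "AB", "PO", "RC", "NE", "MO", "RO")
DEFAULT_FAMILIES = {"FR": GAUSSIAN, "PL": POISSON, "AB": POISSON, "PO": POISSON,
                    "RC": GAUSSIAN, "NE": GAUSSIAN, "MO": GAUSSIAN, "RO": GAUSSIAN}


@dataclass(frozen=True)
class Path:
    source: str
    target: str
    path_id: int


@dataclass
class PathStructure:
    """A directed acyclic path structure with optional moderation terms."""

    paths: list[Path]
    interactions: list[tuple[str, int]] = field(default_factory=list)  # (moderator, path_id)
    correlated_errors: list[tuple[str, str]] = field(default_factory=list)
    families: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_FAMILIES))
    # variables and their exogenous/endogenous roles persist even when
    # selection removes a variable's last path: the missing paths become
    # independence claims
    all_variables: frozenset = None
    exogenous_variables: frozenset = None

    def __post_init__(self) -> None:
        ids = [p.path_id for p in self.paths]
        if len(ids) != len(set(ids)):
            raise ValueError("path ids must be unique")
        known = {p.path_id for p in self.paths}
        for _, pid in self.interactions:
            if pid not in known:
                raise ValueError(f"interaction refers to unknown path id {pid}")
        in_paths = {v for p in self.paths for v in (p.source, p.target)}
        if self.all_variables is None:
            self.all_variables = frozenset(in_paths)
        else:
            self.all_variables = frozenset(self.all_variables) | in_paths
        if self.exogenous_variables is None:
            targets = {p.target for p in self.paths}
            self.exogenous_variables = frozenset(self.all_variables - targets)
        else:
            self.exogenous_variables = frozenset(self.exogenous_variables)
        self.topological_order()                     # raises on cycles

    @property
    def variables(self) -> set[str]:
        return set(self.all_variables)

    def parents(self, var: str) -> list[str]:
        return [p.source for p in self.paths if p.target == var]

    def responses(self) -> list[str]:
        """Endogenous variables in topological order."""
        return [v for v in self.topological_order() if self.parents(v)]

    def path(self, path_id: int) -> Path:
        for p in self.paths:
            if p.path_id == path_id:
                return p
        raise KeyError(path_id)

    def drop_path(self, path_id: int) -> "PathStructure":
        return PathStructure(
            [p for p in self.paths if p.path_id != path_id],
            [(m, pid) for (m, pid) in self.interactions if pid != path_id],
            list(self.correlated_errors),
            dict(self.families),
            all_variables=self.all_variables,
            exogenous_variables=self.exogenous_variables,
        )

    def topological_order(self) -> list[str]:
        nodes = sorted(self.variables)
        parents = {v: set(self.parents(v)) for v in nodes}
        order: list[str] = []
        remaining = set(nodes)
        while remaining:
            ready = sorted(v for v in remaining if not (parents[v] & remaining))
            if not ready:
                raise ValueError("path structure contains a cycle")
            order.extend(ready)
            remaining -= set(ready)
        return order

    def adjacent(self, a: str, b: str) -> bool:
        return any((p.source, p.target) in ((a, b), (b, a)) for p in self.paths)

    # -- serialisation ------------------------------------------------------

    def to_yaml(self, path) -> None:
        doc = {
            "paths": [{"id": p.path_id, "source": p.source, "target": p.target}
                      for p in self.paths],
            "interactions": [{"moderator": m, "path": pid}
                             for m, pid in self.interactions],
            "correlated_errors": [list(pair) for pair in self.correlated_errors],
            "families": dict(self.families),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PathStructure":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(
            [Path(d["source"], d["target"], int(d["id"])) for d in doc["paths"]],
            [(d["moderator"], int(d["path"])) for d in doc.get("interactions", [])],
            [tuple(pair) for pair in doc.get("correlated_errors", [])],
            dict(doc.get("families", DEFAULT_FAMILIES)),
        )


def default_structure() -> PathStructure:
    """The shipped 45-path hypothesis.

    Every island attribute may influence every community and network
    response; floral resources and plant richness feed abundance; abundance
    feeds richness; community structure feeds the architecture metrics; and
    robustness responds to abundance, relative connectance, modularity and
    nestedness (path 45).  Correlated errors (double-headed arrows) join FR
    with PL and the architecture metrics RC, NE, MO with one another: the
    former pair share unmodelled habitat drivers, the latter are computed
    from the same interaction matrix.
    """
    spec_order: list[tuple[str, list[str]]] = [
        ("FR", ["DA", "PE", "DM"]),
        ("PL", ["DA", "PE", "DM"]),
        ("AB", ["DA", "PE", "DM", "FR", "PL"]),
        ("PO", ["DA", "PE", "DM", "FR", "PL", "AB"]),
        ("RC", ["DA", "PE", "DM", "FR", "PL", "AB", "PO"]),
        ("NE", ["DA", "PE", "DM", "FR", "PL", "AB", "PO"]),
        ("MO", ["DA", "PE", "DM", "FR", "PL", "AB", "PO"]),
        ("RO", ["DA", "PE", "DM", "AB", "RC", "MO", "NE"]),
    ]
    paths: list[Path] = []
    pid = 0
    for target, sources in spec_order:
        for source in sources:
            pid += 1
            paths.append(Path(source, target, pid))
    return PathStructure(paths, correlated_errors=[("FR", "PL"), ("RC", "NE"),
                                                   ("RC", "MO"), ("NE", "MO")])


# ---------------------------------------------------------------------------
# design table
# ---------------------------------------------------------------------------

def prepare_design(attributes: dict[str, IslandAttributes],
                   community: dict[tuple[str, str], CommunityMetrics],
                   network: dict[tuple[str, str], NetworkMetrics],
                   negate_area: bool = True) -> pd.DataFrame:
    """One analysis row per (island, site class).

    DA defaults to -ln(area) so that "decreased area" increases as islands
    shrink (``negate_area=False`` flips to +ln(area)); DM = ln(distance);
    PE = 1 for edge rows.  Missing attributes raise; missing network metrics
    for a group leave NaNs (islands whose networks were too sparse).
    """
    rows = []
    for (site_id, site_class), cm in sorted(community.items()):
        if site_id not in attributes:
            raise KeyError(f"no attributes for island {site_id!r}")
        attr = attributes[site_id]
        sign = -1.0 if negate_area else 1.0
        nm = network.get((site_id, site_class))
        rows.append({
            "island": site_id,
            "site_class": site_class,
            "DA": sign * np.log(attr.area_ha),
            "PE": 1.0 if site_class == "edge" else 0.0,
            "DM": np.log(attr.distance_to_mainland_m),
            "FR": cm.floral_resources,
            "PL": cm.plant_richness,
            "AB": cm.pollinator_abundance,
            "PO": cm.pollinator_richness,
            "RC": nm.relative_connectance if nm else np.nan,
            "NE": nm.nodf if nm else np.nan,
            "MO": nm.modularity if nm else np.nan,
            "RO": nm.robustness if nm else np.nan,
        })
    return pd.DataFrame(rows)


def interaction_column(table: pd.DataFrame, moderator: str, source: str) -> pd.Series:
    """Centered-product moderation column ``source:moderator``.

    Continuous factors are mean-centered before the product; the binary edge
    indicator is left as is.
    """
    def centered(col: str) -> np.ndarray:
        v = table[col].to_numpy(dtype=float)
        if set(np.unique(v)) <= {0.0, 1.0}:
            return v
        return v - v.mean()

    return pd.Series(centered(source) * centered(moderator),
                     index=table.index, name=f"{source}:{moderator}")


# ---------------------------------------------------------------------------
# component fits and standardization
# ---------------------------------------------------------------------------

def standardized_coefficients(fit: MixedFit, x: pd.DataFrame, y: np.ndarray) -> pd.Series:
    """Standardized partial regression coefficients beta * sd(x) / sd(y).

    Gaussian responses standardize on their own scale; Poisson responses use
    the ln(y + 0.5) proxy for the response s.d., keeping the coefficient on a
    transparent, family-agnostic scale.
    """
    y = np.asarray(y, dtype=float)
    if fit.family == POISSON:
        sd_y = float(np.std(np.log(y + 0.5), ddof=1))
    else:
        sd_y = float(np.std(y, ddof=1))
    if sd_y == 0:
        raise FitError("response has zero variance; cannot standardize")
    out = {}
    for col in x.columns:
        out[col] = float(fit.params[col]) * float(np.std(x[col].to_numpy(dtype=float),
                                                         ddof=1)) / sd_y
    return pd.Series(out)


@dataclass(frozen=True)
class IndependenceClaim:
    """One d-separation claim: x is independent of y given the conditioners."""

    x: str
    y: str
    conditioning: tuple[str, ...]


def basis_set(structure: PathStructure) -> list[IndependenceClaim]:
    """Shipley's basis set of the structure.

    One claim per non-adjacent variable pair, skipping exogenous-exogenous
    pairs (their covariance is free) and pairs joined by a correlated-error
    arc.  The claim conditions on the union of both variables' parents and
    takes the topologically later variable as the response, since tests in
    non-gaussian families are direction-sensitive.
    """
    order = structure.topological_order()
    rank = {v: i for i, v in enumerate(order)}
    corr = {frozenset(pair) for pair in structure.correlated_errors}
    exog = set(structure.exogenous_variables)
    claims = []
    for a, b in itertools.combinations(sorted(structure.variables), 2):
        if structure.adjacent(a, b) or frozenset((a, b)) in corr:
            continue
        if a in exog and b in exog:
            continue
        if a in exog or b in exog:
            x, y = (a, b) if a in exog else (b, a)
        else:
            x, y = (a, b) if rank[a] < rank[b] else (b, a)
        cond = sorted((set(structure.parents(x)) | set(structure.parents(y)))
                      - {x, y})
        claims.append(IndependenceClaim(x, y, tuple(cond)))
    return claims


@dataclass
class FittedSem:
    """A fitted piecewise SEM: component fits, path table and global fit."""

    structure: PathStructure
    coefficients: pd.DataFrame          # path_id, source, target, raw, se, p, std
    component_fits: dict[str, MixedFit]
    fisher_c: float
    dsep_df: int
    dsep_p: float
    k_params: int
    aic: float
    r2: dict[str, float]

    def std_coefficient(self, path_id: int) -> float:
        row = self.coefficients[self.coefficients["path_id"] == path_id]
        return float(row["std"].iloc[0])


class SemFitter:
    """Fits component and claim models over one analysis table, with caching.

    The cache is keyed on (response, predictor tuple), which makes backward
    selection cheap: removing one path re-fits only the models whose
    predictor sets actually changed.
    """

    def __init__(self, table: pd.DataFrame, families: dict[str, str] | None = None):
        self.table = table.reset_index(drop=True)
        self.families = dict(families or DEFAULT_FAMILIES)
        self._cache: dict[tuple, MixedFit] = {}

    def family(self, var: str) -> str:
        return self.families.get(var, GAUSSIAN)

    def _predictor_frame(self, response: str, structure: PathStructure) -> pd.DataFrame:
        cols = {}
        for src in structure.parents(response):
            cols[src] = self.table[src].astype(float)
        for moderator, pid in structure.interactions:
            p = structure.path(pid)
            if p.target == response:
                col = interaction_column(self.table, moderator, p.source)
                cols[col.name] = col
        return pd.DataFrame(cols)

    def fit_component(self, response: str, predictors: tuple[str, ...]) -> MixedFit:
        key = (response, predictors)
        if key not in self._cache:
            x = pd.DataFrame({c: self.table[c].astype(float) for c in predictors})
            self._cache[key] = fit_mixed(self.table[response].to_numpy(), x,
                                         self.table["island"].to_numpy(),
                                         self.family(response))
        return self._cache[key]

    def fit_response(self, response: str, structure: PathStructure) -> tuple[MixedFit, pd.DataFrame]:
        x = self._predictor_frame(response, structure)
        key = (response, tuple(x.columns))
        if key not in self._cache:
            self._cache[key] = fit_mixed(self.table[response].to_numpy(), x,
                                         self.table["island"].to_numpy(),
                                         self.family(response))
        return self._cache[key], x

    def claim_pvalue(self, claim: IndependenceClaim) -> float:
        """Wald p of x added to y's parent model (same family, same RE)."""
        predictors = tuple(list(claim.conditioning) + [claim.x])
        fit = self.fit_component(claim.y, predictors)
        return float(fit.pvalues[claim.x])

    # -- full SEM -----------------------------------------------------------

    def fishers_c(self, claims: list[IndependenceClaim]) -> tuple[float, int, float]:
        if not claims:
            return 0.0, 0, 1.0
        pvals = []
        for claim in claims:
            try:
                pvals.append(self.claim_pvalue(claim))
            except FitError as exc:
                raise FitError(f"claim {claim.x} _||_ {claim.y} | "
                               f"{claim.conditioning}: {exc}") from exc
        pvals = np.clip(np.asarray(pvals), 1e-300, 1.0)
        c = float(-2.0 * np.log(pvals).sum())
        df = 2 * len(pvals)
        return c, df, float(stats.chi2.sf(c, df))

    def fit_sem(self, structure: PathStructure, compute_dsep: bool = True) -> FittedSem:
        coef_rows = []
        fits: dict[str, MixedFit] = {}
        r2: dict[str, float] = {}
        k_total = 0
        for response in structure.responses():
            fit, x = self.fit_response(response, structure)
            fits[response] = fit
            k_total += fit.k_params
            y = self.table[response].to_numpy(dtype=float)
            std = standardized_coefficients(fit, x, y)
            r2[response] = _pseudo_r2(fit, y)
            for p in structure.paths:
                if p.target != response:
                    continue
                coef_rows.append({
                    "path_id": p.path_id, "source": p.source, "target": p.target,
                    "raw": float(fit.params[p.source]),
                    "se": float(fit.bse[p.source]),
                    "p": float(fit.pvalues[p.source]),
                    "std": float(std[p.source]),
                })
            for moderator, pid in structure.interactions:
                p = structure.path(pid)
                if p.target != response:
                    continue
                name = f"{p.source}:{moderator}"
                coef_rows.append({
                    "path_id": -pid, "source": name, "target": response,
                    "raw": float(fit.params[name]), "se": float(fit.bse[name]),
                    "p": float(fit.pvalues[name]), "std": float(std[name]),
                })
        if compute_dsep:
            c, df, p = self.fishers_c(basis_set(structure))
        else:
            c, df, p = np.nan, 0, np.nan
        coefficients = pd.DataFrame(coef_rows)
        return FittedSem(structure, coefficients, fits, c, df, p, k_total,
                         (c + 2 * k_total) if compute_dsep else np.nan, r2)


def _pseudo_r2(fit: MixedFit, y: np.ndarray) -> float:
    """Squared correlation between conditional fitted values and the response."""
    if fit.fitted is None or np.std(fit.fitted) == 0 or np.std(y) == 0:
        return float("nan")
    return float(np.corrcoef(fit.fitted, y)[0, 1] ** 2)


def fit_sem(structure: PathStructure, table: pd.DataFrame,
            compute_dsep: bool = True) -> FittedSem:
    """Fit every component model of a structure on one analysis table."""
    return SemFitter(table, structure.families).fit_sem(structure, compute_dsep)


def sem_aic(fitted: FittedSem) -> float:
    """SEM-level AIC = Fisher's C + 2 K (K = all estimated parameters)."""
    return float(fitted.fisher_c + 2 * fitted.k_params)


# ---------------------------------------------------------------------------
# backward selection
# ---------------------------------------------------------------------------

def backward_select(initial: PathStructure, table: pd.DataFrame,
                    alpha: float = 0.05) -> FittedSem:
    """Greedy path removal minimising the SEM AIC.

    At each step every directed path's removal is scored by the resulting
    C + 2K; the best removal is accepted while it lowers the AIC, and the
    loop stops at the first step where no removal helps.  Non-significant
    paths may survive.  A final d-separation p <= alpha triggers a warning
    (the structure is missing paths), never an error.  Deterministic: no
    randomness anywhere in the loop.
    """
    fitter = SemFitter(table, initial.families)
    current_struct = initial
    current = fitter.fit_sem(current_struct)
    while True:
        best_aic = current.aic
        best_struct = None
        for p in current_struct.paths:
            cand_struct = current_struct.drop_path(p.path_id)
            try:
                cand = fitter.fit_sem(cand_struct)
            except FitError:
                continue
            if cand.aic < best_aic - 1e-9:
                best_aic = cand.aic
                best_struct = cand_struct
                best_fit = cand
        if best_struct is None:
            break
        current_struct, current = best_struct, best_fit
    if current.dsep_p <= alpha:
        warnings.warn(f"final SEM rejected by d-separation (p = {current.dsep_p:.4f}); "
                      "the structure is likely missing paths", stacklevel=2)
    return current


# ---------------------------------------------------------------------------
# effect decomposition
# ---------------------------------------------------------------------------

@dataclass
class EffectsTable:
    """Direct/indirect/total standardized effects with bootstrap CIs."""

    effects: pd.DataFrame       # source, response, effect, estimate, ci_low, ci_high
    n_boot: int
    n_failed: int


def _std_map(fitted: FittedSem) -> dict[tuple[str, str], float]:
    return {(row.source, row.target): row.std
            for row in fitted.coefficients.itertuples()
            if row.path_id > 0}


def path_tracing(std: dict[tuple[str, str], float], source: str,
                 response: str) -> tuple[float, float]:
    """(direct, indirect) standardized effect of source on response.

    Direct is the source->response coefficient (0 if absent); indirect sums
    the coefficient products over every directed compound path.  Moderation
    terms are not traced.
    """
    children: dict[str, list[tuple[str, float]]] = {}
    for (s, t), b in std.items():
        children.setdefault(s, []).append((t, b))

    def walk(node: str, prod: float, length: int) -> float:
        total = 0.0
        for t, b in children.get(node, []):
            if t == response:
                if length >= 1:            # compound path only
                    total += prod * b
            else:
                total += walk(t, prod * b, length + 1)
        return total

    direct = std.get((source, response), 0.0)
    indirect = walk(source, 1.0, 0)
    return direct, indirect


def effects_decomposition(fitted: FittedSem, table: pd.DataFrame,
                          n_boot: int = 1000, seed: int = 0,
                          max_failed_frac: float = 0.10) -> EffectsTable:
    """Decompose every (exogenous-or-upstream, response) pair's effects.

    Point estimates come from the fitted model's standardized coefficients;
    intervals from a cluster bootstrap that resamples islands with
    replacement, refits the fixed structure and re-traces the paths.
    """
    structure = fitted.structure
    std = _std_map(fitted)
    pairs = _effect_pairs(structure)

    point = {}
    for source, response in pairs:
        d, i = path_tracing(std, source, response)
        point[(source, response)] = (d, i, d + i)

    islands = table["island"].unique()
    base = table.reset_index(drop=True)
    block_rows = [np.flatnonzero(base["island"].to_numpy() == isl)
                  for isl in islands]
    boots: dict[tuple[str, str], list[tuple[float, float, float]]] = \
        {pair: [] for pair in pairs}
    n_failed = 0
    for b in range(n_boot):
        rng = np.random.default_rng((seed, b))
        picks = rng.choice(len(islands), size=len(islands), replace=True)
        rows = np.concatenate([block_rows[i] for i in picks])
        boot_table = base.iloc[rows].reset_index(drop=True)
        # resampled copies of one island get distinct group labels
        boot_table["island"] = np.repeat(
            [f"boot{rep}" for rep in range(len(picks))],
            [len(block_rows[i]) for i in picks])
        try:
            boot_fit = SemFitter(boot_table, structure.families).fit_sem(
                structure, compute_dsep=False)
        except FitError:
            n_failed += 1
            continue
        boot_std = _std_map(boot_fit)
        for pair in pairs:
            d, i = path_tracing(boot_std, *pair)
            boots[pair].append((d, i, d + i))
    if n_boot and n_failed > max_failed_frac * n_boot:
        raise FitError(f"{n_failed}/{n_boot} bootstrap refits failed")

    rows = []
    for pair in pairs:
        arr = np.asarray(boots[pair]) if boots[pair] else np.empty((0, 3))
        for k, effect in enumerate(("direct", "indirect", "total")):
            lo, hi = (np.percentile(arr[:, k], [2.5, 97.5])
                      if len(arr) else (np.nan, np.nan))
            rows.append({
                "source": pair[0], "response": pair[1], "effect": effect,
                "estimate": point[pair][k], "ci_low": lo, "ci_high": hi,
            })
    return EffectsTable(pd.DataFrame(rows), n_boot, n_failed)


def _effect_pairs(structure: PathStructure) -> list[tuple[str, str]]:
    """All (ancestor, response) pairs connected by at least one directed path."""
    std_edges = {(p.source, p.target) for p in structure.paths}
    reach: dict[str, set[str]] = {}

    def descendants(v: str) -> set[str]:
        if v not in reach:
            out: set[str] = set()
            for (s, t) in std_edges:
                if s == v:
                    out.add(t)
                    out |= descendants(t)
            reach[v] = out
        return reach[v]

    pairs = []
    for v in sorted(structure.variables):
        for r in sorted(descendants(v)):
            pairs.append((v, r))
    return pairs
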