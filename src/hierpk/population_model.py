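"""Population-level structure for the four kinetic parameters.

Each profile-level parameter theta_ijkl (l indexed 0..3 in code for t_max,
MCR, a, b) follows

    theta_ijkl ~ LogNormal(eta_ijkl, sigma_theta_l^2)   l in {0, 1}
    theta_ijkl ~ Normal(eta_ijkl, sigma_theta_l^2)      l in {2, 3}

with a linear predictor eta whose intercept varies with the hierarchy level:

    one    : eta = phi_l                         (+ W beta)
    two    : eta = psi_il,      psi ~ N(phi, sigma_psi^2)
    threeV : eta = chiV_ijl,    chiV ~ N(psi, sigma_chiV^2)
    threeM : eta = chiM_ikl,    chiM ~ N(psi, sigma_chiM^2)

Covariates enter through three separately selected groups (continuous,
binary, study-by-mealtime interaction), each a reversible-jump block with its
own coefficient prior sd Delta_beta_l / (1.96 * Delta_x); Delta_x = 1 for
binary and interaction indicators and 2*1.96 for standardized continuous
covariates.  Model-space priors make all distinct, identifiable covariate
models within a group equally probable a priori.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .trial_data import CovariateDesign, Dataset

__all__ = [
    "LEVELS",
    "GROUPS",
    "LOGNORMAL_PARAMS",
    "PARAM_NAMES",
    "ModelSpec",
    "PopulationState",
    "GroupPriors",
    "HierarchyIndex",
    "eta",
    "eta_vector",
    "random_effect_logpdf",
    "coefficient_prior_sd",
    "model_prior_logpmf",
    "interaction_q_pmf",
    "default_delta_beta",
]

LEVELS = ("one", "two", "threeV", "threeM")
GROUPS = ("continuous", "binary", "interaction")
LOGNORMAL_PARAMS = (0, 1)  # t_max and MCR: log-normal random effects
PARAM_NAMES = ("t_max", "MCR", "a", "b")

# q prior over the number of included interaction indicators; q = 4 would be
# unidentifiable and the four q = 3 models are equivalent, so mass 1/12 is
# spread over each of the 12 distinct identifiable models.
INTERACTION_Q_PMF = (1.0 / 12.0, 4.0 / 12.0, 6.0 / 12.0, 1.0 / 12.0, 0.0)
MAX_INTERACTION_Q = 3

PHI_PRIOR_SD = (100.0, 100.0, 1000.0, 1000.0)  # log-scale for l = 0, 1
SD_PRIOR_UPPER = 100.0


def interaction_q_pmf(q: int) -> float:
    return INTERACTION_Q_PMF[q] if 0 <= q <= 4 else 0.0


@dataclass(frozen=True)
class ModelSpec:
    """Choice of hierarchy level, covariate switch and prior scaling.

    delta_beta is the width of the plausible range for each (log-)parameter,
    used to scale the coefficient priors; by default it is derived from the
    spread of first-stage posterior medians (see :func:`default_delta_beta`).
    """

    level: str = "one"
    covariates_on: bool = False
    delta_beta: tuple[float, float, float, float] | None = None

    def __post_init__(self):
        if self.level not in LEVELS:
            raise ValueError(f"level must be one of {LEVELS}")
        if self.covariates_on and self.delta_beta is not None:
            if any(d <= 0 for d in self.delta_beta):
                raise ValueError("delta_beta entries must be positive")

    @property
    def n_levels(self) -> int:
        return {"one": 1, "two": 2, "threeV": 3, "threeM": 3}[self.level]


@dataclass
class GroupPriors:
    """Per-group covariate selection priors for one kinetic parameter."""

    coef_sd: dict[str, float]  # group -> coefficient prior sd
    n_columns: dict[str, int]  # group -> c_G


def coefficient_prior_sd(delta_beta: float, group: str) -> float:
    """Prior sd Delta_beta / (1.96 * Delta_x) for a coefficient in ``group``.

    Delta_x = 1 for binary and interaction indicators, 2*1.96 = 3.92 for
    standardized continuous covariates (their values span about +/- 1.96 sd).
    """
    if delta_beta <= 0:
        raise ValueError("delta_beta must be positive")
    if group == "continuous":
        dx = 2.0 * 1.96
    elif group in ("binary", "interaction"):
        dx = 1.0
    else:
        raise ValueError(f"unknown covariate group {group!r}")
    return delta_beta / (1.96 * dx)


def _log_binom(n: int, k: int) -> float:
    return float(gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1))


def model_prior_logpmf(group: str, q: int, gamma, c: int) -> float:
    """Log prior of a covariate model (q, gamma) within a group.

    p(gamma | q) is uniform over the C(c, q) subsets of size q.  p(q) is
    Binomial(c, 1/2) for the continuous and binary groups, and the tabulated
    pmf (1/12, 4/12, 6/12, 1/12, 0) for the interaction group, which makes
    every distinct identifiable model in the group equally probable.
    """
    gamma = np.asarray(gamma, dtype=int)
    if q != len(gamma) or len(set(gamma.tolist())) != q:
        raise ValueError("gamma must contain q unique column indices")
    if q < 0 or q > c or (len(gamma) and (gamma.min() < 0 or gamma.max() >= c)):
        return -math.inf
    if group == "interaction":
        pq = interaction_q_pmf(q)
        if pq == 0.0:
            return -math.inf
        return math.log(pq) - _log_binom(c, q)
    if group in ("continuous", "binary"):
        # Binomial(c, 1/2) on q, then uniform over subsets
        log_pq = _log_binom(c, q) - c * math.log(2.0)
        return log_pq - _log_binom(c, q)
    raise ValueError(f"unknown covariate group {group!r}")


@dataclass
class SelectionState:
    """Reversible-jump state (q, gamma, beta) for one (parameter, group)."""

    gamma: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    beta: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self):
        self.gamma = np.asarray(self.gamma, dtype=int)
        self.beta = np.asarray(self.beta, dtype=float)
        if len(self.gamma) != len(self.beta):
            raise ValueError("gamma and beta must have equal length")
        if len(set(self.gamma.tolist())) != len(self.gamma):
            raise ValueError("gamma entries must be unique")

    @property
    def q(self) -> int:
        return len(self.gamma)

    def copy(self) -> "SelectionState":
        return SelectionState(self.gamma.copy(), self.beta.copy())


class HierarchyIndex:
    """Integer index arrays mapping profiles to women and visit/meal cells."""

    def __init__(self, dataset: Dataset, profile_ids=None):
        pids = list(profile_ids) if profile_ids is not None else dataset.included_ids
        keys = [dataset.profiles[p].key for p in pids]
        self.profile_ids = pids
        women = sorted({k.woman for k in keys})
        self.women = women
        w_of = {w: i for i, w in enumerate(women)}
        self.woman_of_profile = np.array([w_of[k.woman] for k in keys], dtype=int)
        vcells = sorted({(k.woman, k.visit) for k in keys})
        mcells = sorted({(k.woman, k.meal) for k in keys})
        self.visit_cells = vcells
        self.meal_cells = mcells
        v_of = {c: i for i, c in enumerate(vcells)}
        m_of = {c: i for i, c in enumerate(mcells)}
        self.visit_cell_of_profile = np.array(
            [v_of[(k.woman, k.visit)] for k in keys], dtype=int
        )
        self.meal_cell_of_profile = np.array(
            [m_of[(k.woman, k.meal)] for k in keys], dtype=int
        )
        self.woman_of_visit_cell = np.array([w_of[w] for w, _ in vcells], dtype=int)
        self.woman_of_meal_cell = np.array([w_of[w] for w, _ in mcells], dtype=int)

    @property
    def n_profiles(self) -> int:
        return len(self.profile_ids)

    @property
    def n_women(self) -> int:
        return len(self.women)

    def cells(self, level: str):
        """(cell_of_profile, woman_of_cell) for a three-level model."""
        if level == "threeV":
            return self.visit_cell_of_profile, self.woman_of_visit_cell
        if level == "threeM":
            return self.meal_cell_of_profile, self.woman_of_meal_cell
        raise ValueError("cells are defined for three-level models only")


@dataclass
class PopulationState:
    """Full population-parameter state Omega for a given ModelSpec.

    phi: global intercepts (4,); psi: woman intercepts (n_women, 4) for
    levels >= two; chi: visit- or meal-cell intercepts (n_cells, 4) for
    three-level models; sigma_*: component sds in [0, 100]; selection[l][G]:
    reversible-jump state per parameter and covariate group.
    """

    phi: np.ndarray
    sigma_theta: np.ndarray
    psi: np.ndarray | None = None
    sigma_psi: np.ndarray | None = None
    chi: np.ndarray | None = None
    sigma_chi: np.ndarray | None = None
    selection: list[dict[str, SelectionState]] | None = None

    def copy(self) -> "PopulationState":
        return PopulationState(
            phi=self.phi.copy(),
            sigma_theta=self.sigma_theta.copy(),
            psi=None if self.psi is None else self.psi.copy(),
            sigma_psi=None if self.sigma_psi is None else self.sigma_psi.copy(),
            chi=None if self.chi is None else self.chi.copy(),
            sigma_chi=None if self.sigma_chi is None else self.sigma_chi.copy(),
            selection=None
            if self.selection is None
            else [{g: s.copy() for g, s in d.items()} for d in self.selection],
        )

    def covariate_contribution(self, l: int, X: np.ndarray) -> np.ndarray:
        """W_ijkl . beta_l summed over the three groups, for all rows of X."""
        out = np.zeros(X.shape[0])
        if self.selection is None:
            return out
        for sel in self.selection[l].values():
            if sel.q:
                out += X[:, sel.gamma] @ sel.beta
        return out


def eta_vector(
    state: PopulationState,
    spec: ModelSpec,
    l: int,
    index: HierarchyIndex,
    design: CovariateDesign | None,
) -> np.ndarray:
    """Linear predictor eta_ijkl for every profile, in index order."""
    if spec.level == "one":
        base = np.full(index.n_profiles, state.phi[l])
    elif spec.level == "two":
        base = state.psi[index.woman_of_profile, l]
    else:
        cell_of_profile, _ = index.cells(spec.level)
        base = state.chi[cell_of_profile, l]
    if spec.covariates_on and design is not None:
        base = base + state.covariate_contribution(l, design.X)
    return base


def eta(
    level: str,
    indices: tuple[int, int, int],
    l: int,
    state: PopulationState,
    design_row: np.ndarray | None = None,
) -> float:
    """Scalar linear predictor for one profile.

    ``indices`` are positional indices (woman index, cell index, profile row
    in the design); the relevant entry depends on the level.
    """
    i, cell, row = indices
    if level == "one":
        base = state.phi[l]
    elif level == "two":
        base = state.psi[i, l]
    elif level in ("threeV", "threeM"):
        base = state.chi[cell, l]
    else:
        raise ValueError(f"unknown level {level!r}")
    if design_row is not None and state.selection is not None:
        for sel in state.selection[l].values():
            if sel.q:
                base += float(design_row[sel.gamma] @ sel.beta)
    return float(base)


_LOG_2PI = math.log(2.0 * math.pi)


def random_effect_logpdf(theta: float, eta_val: float, sd: float, l: int) -> float:
    """Log density of theta_ijkl: log-normal for t_max and MCR, normal for
    a and b."""
    if sd <= 0:
        raise ValueError("sd must be positive")
    if l in LOGNORMAL_PARAMS:
        if theta <= 0:
            return -math.inf
        z = (math.log(theta) - eta_val) / sd
        return -0.5 * _LOG_2PI - math.log(sd) - math.log(theta) - 0.5 * z * z
    z = (theta - eta_val) / sd
    return -0.5 * _LOG_2PI - math.log(sd) - 0.5 * z * z


def default_delta_beta(stage1_medians: np.ndarray) -> tuple[float, ...]:
    """Plausible-range widths from first-stage posterior medians.

    ``stage1_medians`` is (n_profiles, 4) on the natural scale; the range is
    taken on the log scale for t_max and MCR.  Lacking other prior knowledge,
    the spread of independently fitted profiles is the natural scale for how
    large a covariate effect could plausibly be (at the cost of a mild double
    use of the data).
    """
    med = np.asarray(stage1_medians, dtype=float)
    out = []
    for l in range(4):
        v = np.log(med[:, l]) if l in LOGNORMAL_PARAMS else med[:, l]
        width = float(v.max() - v.min())
        if width <= 0:
            raise ValueError(f"degenerate stage-1 median range for parameter {l}")
        out.append(width)
    return tuple(out)


def make_group_priors(
    spec: ModelSpec, design: CovariateDesign, delta_beta
) -> list[GroupPriors]:
    """GroupPriors per kinetic parameter for the given design."""
    out = []
    for l in range(4):
        coef_sd = {}
        n_cols = {}
        for g in GROUPS:
            cols = design.columns_of(g)
            n_cols[g] = len(cols)
            coef_sd[g] = coefficient_prior_sd(delta_beta[l], g) if len(cols) else 0.0
        out.append(GroupPriors(coef_sd=coef_sd, n_columns=n_cols))
    return out


def initial_population_state(
    spec: ModelSpec,
    index: HierarchyIndex,
    v_init: np.ndarray,
) -> PopulationState:
    """Starting state: intercepts from the per-profile values ``v_init``
    ((n, 4), log scale for l = 0, 1), sds from their dispersion, empty
    covariate models."""
    phi = v_init.mean(axis=0)
    disp = np.maximum(v_init.std(axis=0, ddof=0), 1e-3)
    psi = chi = sigma_psi = sigma_chi = None
    if spec.n_levels >= 2:
        psi = np.tile(phi, (index.n_women, 1))
        for w in range(index.n_women):
            rows = index.woman_of_profile == w
            psi[w] = v_init[rows].mean(axis=0)
        sigma_psi = disp.copy()
    if spec.n_levels == 3:
        cell_of_profile, _ = index.cells(spec.level)
        n_cells = cell_of_profile.max() + 1
        chi = np.zeros((n_cells, 4))
        for c in range(n_cells):
            rows = cell_of_profile == c
            chi[c] = v_init[rows].mean(axis=0)
        sigma_chi = disp.copy()
    selection = [
        {g: SelectionState() for g in GROUPS} for _ in range(4)
    ]
    return PopulationState(
        phi=phi.copy(),
        sigma_theta=disp.copy(),
        psi=psi,
        sigma_psi=sigma_psi,
        chi=chi,
        sigma_chi=sigma_chi,
        selection=selection,
    )
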