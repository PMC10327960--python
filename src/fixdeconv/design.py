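"""Design matrices for regression-based deconvolution of continuous EEG.

Two stages.  First, a *mass-univariate* design: one row per modeling event
(fixation onsets and stimulus onsets), with an intercept, treatment-coded
fixation categories and cubic B-spline expansions of the continuous
oculomotor covariates.  Second, *time expansion*: every mass-design entry is
replicated at a grid of time lags around its event, producing a sparse
matrix over the samples of the continuous recording.  One linear model over
that matrix estimates all event-locked responses simultaneously, which is
what disentangles temporally overlapping responses of successive fixations.

Spline convention: a covariate modeled with ``n_basis`` splines uses a
clamped cubic B-spline basis whose knots sit on ``n_basis - 2`` equally
spaced quantiles of the fitting data (endpoints included; for five splines
these are the 0th/50th/100th percentiles).  The basis functions sum to one
everywhere in range, so in a model that already has an intercept one column
per covariate is dropped for identifiability: five splines contribute four
columns, and the default fixation model has

    1 (intercept) + 3 (category dummies) + 5 covariates x 4 = 24

columns, plus one stimulus intercept: 25 predictors in total.  With a
-200..+500 ms window at 250 Hz each predictor expands into 175 lagged
copies, 4375 columns overall.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.interpolate import BSpline

from .events import CATEGORIES, OTHER

FIXATION = "fixation"
STIMULUS = "stimulus"

DEFAULT_WINDOW = (-0.2, 0.5)
DEFAULT_SPLINE_COVARIATES = (
    "fixation_rank", "fixation_duration",
    "incoming_saccade_size", "outgoing_saccade_size", "y",
)


# ---------------------------------------------------------------------------
# spline basis

@dataclass
class SplineBasis:
    """Clamped cubic B-spline basis fitted to a covariate sample."""

    knots: np.ndarray          # full knot vector, boundary multiplicity 4
    n_basis: int
    boundary: tuple[float, float]
    dropped_column: int = 0    # removed for identifiability
    degree: int = 3

    @property
    def interior_knots(self) -> np.ndarray:
        """The quantile-placed knot points (boundaries included)."""
        return self.knots[self.degree: -self.degree]

    def evaluate(self, values, drop: bool = True) -> np.ndarray:
        """Basis functions at ``values`` (clamped to the fitting range)."""
        x = np.clip(np.asarray(values, dtype=float), *self.boundary)
        b = BSpline.design_matrix(x, self.knots, self.degree).toarray()
        if drop:
            b = np.delete(b, self.dropped_column, axis=1)
        return b


def make_spline_basis(values, n_basis: int = 5) -> SplineBasis:
    """Fit a spline basis: knots on ``n_basis - 2`` quantiles of ``values``.

    Requires ``n_basis >= 4`` (the clamped cubic construction) and at least
    ``n_basis`` distinct data values.
    """
    if n_basis < 4:
        raise ValueError("n_basis must be >= 4 for a clamped cubic basis")
    values = np.asarray(values, dtype=float)
    if np.unique(values).size < n_basis:
        raise ValueError(
            f"need >= {n_basis} distinct values to place spline knots, "
            f"got {np.unique(values).size}")
    probs = np.linspace(0, 1, n_basis - 2)
    qs = np.quantile(values, probs)
    lo, hi = float(qs[0]), float(qs[-1])
    knots = np.r_[[lo] * 3, qs, [hi] * 3]
    return SplineBasis(knots=knots, n_basis=n_basis, boundary=(lo, hi))


# ---------------------------------------------------------------------------
# model formula

@dataclass(frozen=True)
class Intercept:
    name: str = "intercept"


@dataclass(frozen=True)
class Categorical:
    name: str
    levels: tuple[str, ...]
    reference: str

    def __post_init__(self):
        if self.reference not in self.levels:
            raise ValueError(f"reference {self.reference!r} not in levels")

    @property
    def coded_levels(self) -> tuple[str, ...]:
        return tuple(l for l in self.levels if l != self.reference)


@dataclass(frozen=True)
class Spline:
    name: str
    n_basis: int = 5

    def __post_init__(self):
        if self.n_basis < 4:
            raise ValueError("n_basis must be >= 4")


Term = Intercept | Categorical | Spline


@dataclass(frozen=True)
class ModelFormula:
    """Ordered terms per event type (Wilkinson-style ``y ~ 1 + ...``)."""

    terms: dict[str, tuple[Term, ...]]

    def __post_init__(self):
        for etype, terms in self.terms.items():
            if sum(isinstance(t, Intercept) for t in terms) > 1:
                raise ValueError(f"{etype}: at most one intercept")

    def n_columns(self) -> int:
        p = 0
        for terms in self.terms.values():
            for t in terms:
                if isinstance(t, Intercept):
                    p += 1
                elif isinstance(t, Categorical):
                    p += len(t.levels) - 1
                else:
                    p += t.n_basis - 1
        return p


def formula_from_yaml(path) -> ModelFormula:
    """Read a model formula from a YAML config.

    Layout mirrors the per-event-type notation::

        fixation:
          - intercept
          - categorical: {name: category, levels: [precursor, refixation,
                          ordinary, other], reference: other}
          - spline: {name: fixation_rank, n_basis: 5}
        stimulus:
          - intercept
    """
    import yaml
    with open(path) as f:
        spec = yaml.safe_load(f)
    terms: dict[str, tuple[Term, ...]] = {}
    for etype, items in spec.items():
        parsed: list[Term] = []
        for item in items:
            if item == "intercept":
                parsed.append(Intercept())
            elif isinstance(item, dict) and "categorical" in item:
                d = item["categorical"]
                parsed.append(Categorical(d["name"], tuple(d["levels"]),
                                          d["reference"]))
            elif isinstance(item, dict) and "spline" in item:
                d = item["spline"]
                parsed.append(Spline(d["name"], int(d.get("n_basis", 5))))
            else:
                raise ValueError(f"unrecognized formula term: {item!r}")
        terms[etype] = tuple(parsed)
    return ModelFormula(terms)


def default_formula(
        spline_covariates: tuple[str, ...] = DEFAULT_SPLINE_COVARIATES,
        n_basis: int = 5,
        categories: tuple[str, ...] = CATEGORIES,
        reference: str = OTHER) -> ModelFormula:
    """The standard model: fixation ~ 1 + category + splines; stimulus ~ 1."""
    fix_terms: list[Term] = [Intercept(),
                             Categorical("category", categories, reference)]
    fix_terms += [Spline(c, n_basis) for c in spline_covariates]
    return ModelFormula({FIXATION: tuple(fix_terms), STIMULUS: (Intercept(),)})


# ---------------------------------------------------------------------------
# mass-univariate design

@dataclass(frozen=True)
class ColumnInfo:
    event_type: str
    term: str
    kind: str       # "intercept" | "dummy" | "spline"
    detail: str     # level name or basis index


@dataclass
class MassDesign:
    X: np.ndarray                      # n_events x P
    columns: list[ColumnInfo]
    formula: ModelFormula
    bases: dict[str, SplineBasis]      # fitted basis per spline covariate
    event_types: np.ndarray            # per-row event type

    @property
    def P(self) -> int:
        return self.X.shape[1]


def build_mass_design(events: pd.DataFrame, formula: ModelFormula) -> MassDesign:
    """Construct the mass-univariate design matrix.

    ``events`` needs an ``event_type`` column; fixation rows additionally
    need ``category`` and every spline covariate (already imputed — no NaN).
    Rows of one event type are zero in the other type's columns.
    """
    etypes = events["event_type"].to_numpy()
    n = len(events)
    blocks: list[np.ndarray] = []
    columns: list[ColumnInfo] = []
    bases: dict[str, SplineBasis] = {}

    for etype, terms in formula.terms.items():
        mask = etypes == etype
        for term in terms:
            if isinstance(term, Intercept):
                col = np.zeros((n, 1))
                col[mask, 0] = 1.0
                blocks.append(col)
                columns.append(ColumnInfo(etype, "intercept", "intercept", ""))
            elif isinstance(term, Categorical):
                values = events.loc[mask, term.name]
                unknown = set(values) - set(term.levels)
                if unknown:
                    raise ValueError(f"unknown {term.name} levels: {unknown}")
                for level in term.coded_levels:
                    col = np.zeros((n, 1))
                    col[mask, 0] = (values == level).to_numpy(float)
                    blocks.append(col)
                    columns.append(ColumnInfo(etype, term.name, "dummy", level))
            else:  # Spline
                vals = events.loc[mask, term.name].to_numpy(float)
                if np.isnan(vals).any():
                    raise ValueError(
                        f"NaN in spline covariate {term.name!r}; impute first")
                basis = make_spline_basis(vals, term.n_basis)
                bases[term.name] = basis
                b = np.zeros((n, term.n_basis - 1))
                b[mask] = basis.evaluate(vals)
                blocks.append(b)
                columns += [ColumnInfo(etype, term.name, "spline", str(i))
                            for i in range(1, term.n_basis)]
    X = np.hstack(blocks) if blocks else np.zeros((n, 0))
    assert X.shape[1] == formula.n_columns()
    return MassDesign(X=X, columns=columns, formula=formula, bases=bases,
                      event_types=etypes)


# ---------------------------------------------------------------------------
# time expansion

@dataclass
class ExpandedDesign:
    """Sparse time-expanded design over continuous-EEG samples.

    Column layout is predictor-major: column ``p * L + l`` is mass predictor
    ``p`` lagged by ``lag_offsets[l]`` samples.
    """

    X: sp.csr_matrix               # n_samples x (P * L)
    window: tuple[float, float]    # seconds, half-open on the right
    sampling_rate: float
    lag_offsets: np.ndarray        # L sample offsets (round(t_min*fs) ...)
    columns: list[ColumnInfo]      # the P mass columns
    bases: dict[str, SplineBasis]
    formula: ModelFormula
    zeroed_intervals: list[tuple[int, int]] = field(default_factory=list)

    @property
    def L(self) -> int:
        return len(self.lag_offsets)

    @property
    def P(self) -> int:
        return len(self.columns)

    @property
    def lag_times(self) -> np.ndarray:
        """Lag axis in seconds."""
        return self.lag_offsets / self.sampling_rate

    def save_triplets(self, path) -> None:
        """Write the nonzeros as a ``row col value`` text file (debugging)."""
        coo = self.X.tocoo()
        with open(path, "w") as f:
            f.write(f"# {self.X.shape[0]} {self.X.shape[1]} {self.X.nnz}\n")
            for r, c, v in zip(coo.row, coo.col, coo.data):
                f.write(f"{r} {c} {v:.17g}\n")


def n_lags(window: tuple[float, float], sampling_rate: float) -> int:
    """Half-open lag count: 700 ms at 250 Hz -> exactly 175 lags."""
    return int(round(window[1] * sampling_rate) - round(window[0] * sampling_rate))


def time_expand(mass: MassDesign, event_times, window: tuple[float, float],
                sampling_rate: float, n_samples: int) -> ExpandedDesign:
    """Time-expand the mass design around each event.

    Each nonzero mass entry (event e, predictor p) is copied to rows
    ``round(t_e * fs) + lag`` for every lag in the half-open sample window,
    one lag per expanded column.  Rows falling outside the recording are
    truncated; overlapping events sum into shared rows.
    """
    t_min, t_max = window
    if not t_min < t_max:
        raise ValueError("window must satisfy t_min < t_max")
    event_times = np.asarray(event_times, dtype=float)
    if len(event_times) != mass.X.shape[0]:
        raise ValueError("event_times length must match mass design rows")
    fs = float(sampling_rate)
    start = int(round(t_min * fs))
    L = n_lags(window, fs)
    offsets = start + np.arange(L)
    P = mass.P
    shape = (n_samples, P * L)

    if len(event_times) == 0:
        warnings.warn("empty event list: all-zero design")
        return ExpandedDesign(X=sp.csr_matrix(shape), window=window,
                              sampling_rate=fs, lag_offsets=offsets,
                              columns=mass.columns, bases=mass.bases,
                              formula=mass.formula)

    ev_samples = np.round(event_times * fs).astype(int)
    e_idx, p_idx = np.nonzero(mass.X)
    vals = mass.X[e_idx, p_idx]
    # broadcast every nonzero across the L lags
    rows = (ev_samples[e_idx][:, None] + offsets[None, :]).ravel()
    cols = (p_idx[:, None] * L + np.arange(L)[None, :]).ravel()
    data = np.repeat(vals, L)
    keep = (rows >= 0) & (rows < n_samples)
    X = sp.coo_matrix((data[keep], (rows[keep], cols[keep])), shape=shape).tocsr()
    return ExpandedDesign(X=X, window=window, sampling_rate=fs,
                          lag_offsets=offsets, columns=mass.columns,
                          bases=mass.bases, formula=mass.formula)


def zero_out_intervals(expanded: ExpandedDesign,
                       intervals) -> ExpandedDesign:
    """Zero entire sample rows (half-open ``[start, stop)`` sample ranges).

    Used to exclude irrelevant or bad intervals (inter-trial gaps, breaks,
    bad eye-tracking stretches) from the model while preserving the timing
    of the continuous recording.  Dimensions are unchanged.
    """
    n = expanded.X.shape[0]
    mask = np.ones(n, dtype=bool)
    norm: list[tuple[int, int]] = []
    for start, stop in intervals:
        if stop < start:
            raise ValueError(f"inverted interval ({start}, {stop})")
        start_c, stop_c = max(0, int(start)), min(n, int(stop))
        mask[start_c:stop_c] = False
        norm.append((int(start), int(stop)))
    d = sp.diags(mask.astype(float))
    X = (d @ expanded.X).tocsr()
    X.eliminate_zeros()
    return replace(expanded, X=X,
                   zeroed_intervals=expanded.zeroed_intervals + norm)
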