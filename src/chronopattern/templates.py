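"""Temporal template library, template assignment and pattern enrichment.

Each differentially expressed gene's standardized time profile is matched by
Pearson correlation against a library of canonical temporal shapes: a flat
shape (code ``00``), single-timepoint changes at the first and last hour,
plateaus switching on at intermediate hours, single-timepoint spikes at
interior hours, and a linear ramp.  Every non-flat shape comes in two
vertically mirrored orientations, ``a`` and its negation ``b``.  Crossing the
shapes with three drug-effect classes (up / down / unchanged) yields the full
pattern library: for a six-timepoint design, 21 shapes and 63 patterns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .anova import AnovaRecord

logger = logging.getLogger(__name__)

#: Drug-effect classes in canonical order.
DRUG_CLASSES = ("up", "down", "unchanged")

#: Display arrows for the drug-effect classes.
DRUG_ARROWS = {"up": "↑", "down": "↓", "unchanged": "↔"}


@dataclass(frozen=True)
class TemporalShape:
    """A canonical temporal shape: a code like ``04a`` and its vector."""

    code: str
    vector: tuple[float, ...]

    @property
    def is_flat(self) -> bool:
        return self.code == "00"

    def zscored(self) -> np.ndarray:
        v = np.asarray(self.vector, dtype=float)
        sd = v.std()
        if sd == 0:
            return np.zeros_like(v)
        return (v - v.mean()) / sd


@dataclass
class TemplateLibrary:
    """All temporal shapes for a given timepoint grid, crossed with drug classes."""

    timepoints: tuple[float, ...]
    shapes: list[TemporalShape]

    @property
    def n_timepoints(self) -> int:
        return len(self.timepoints)

    @property
    def shape_codes(self) -> list[str]:
        return [s.code for s in self.shapes]

    @property
    def patterns(self) -> list[str]:
        """Pattern ids: every (shape, drug-effect class) combination."""
        return [pattern_id(s.code, c) for s in self.shapes for c in DRUG_CLASSES]

    def shape(self, code: str) -> TemporalShape:
        for s in self.shapes:
            if s.code == code:
                return s
        raise KeyError(code)


def pattern_id(shape_code: str, drug_class: str) -> str:
    if drug_class not in DRUG_CLASSES:
        raise ValueError(f"unknown drug class {drug_class!r}")
    return f"{shape_code}({drug_class})"


def build_template_library(timepoints) -> TemplateLibrary:
    """Build the canonical shape library for an ordered timepoint grid.

    For T timepoints the non-flat families are: a change at the first point,
    T-3 plateaus switching on at an intermediate point, a change at the last
    point, T-2 spikes at interior points, and a linear ramp — each in an 'a'
    orientation and its negated 'b' reflection — plus the flat shape ``00``.
    For T = 6 this gives the familiar codes 00, 01a/b ... 10a/b (21 shapes).
    """
    tp = tuple(float(t) for t in timepoints)
    T = len(tp)
    if T < 3:
        raise ValueError(f"need at least 3 timepoints to define shapes, got {T}")
    if list(tp) != sorted(set(tp)):
        raise ValueError("timepoints must be strictly increasing")

    base: list[np.ndarray] = []
    # change at the first timepoint
    v = np.zeros(T)
    v[0] = 1.0
    base.append(v)
    # plateaus reached through a graded (half-height) onset at hour 2..T-2;
    # a hard step at hour 2 would be exactly collinear with the mirrored
    # first-point change, making the two patterns indistinguishable by
    # Pearson correlation
    for onset in range(1, T - 2):
        v = np.zeros(T)
        v[onset] = 0.5
        v[onset + 1:] = 1.0
        base.append(v)
    # change at the last timepoint
    v = np.zeros(T)
    v[-1] = 1.0
    base.append(v)
    # spikes at interior timepoints
    for pos in range(1, T - 1):
        v = np.zeros(T)
        v[pos] = 1.0
        base.append(v)
    # linear ramp
    base.append(np.arange(T, dtype=float) / (T - 1))

    shapes = [TemporalShape("00", (0.0,) * T)]
    for i, vec in enumerate(base, start=1):
        shapes.append(TemporalShape(f"{i:02d}a", tuple(vec)))
        shapes.append(TemporalShape(f"{i:02d}b", tuple(-vec)))
    return TemplateLibrary(tp, shapes)


# ---------------------------------------------------------------------------
# Assignment
# ---------------------------------------------------------------------------

@dataclass
class TemplateAssignment:
    """Best-fitting shape for one gene profile."""

    gene: str
    shape: str | None          # shape code, or None when unassigned
    r: float                   # Pearson r with the assigned shape (best r if unassigned)
    drug_class: str = "unchanged"
    sector: str = ""

    @property
    def assigned(self) -> bool:
        return self.shape is not None

    @property
    def pattern(self) -> str | None:
        return pattern_id(self.shape, self.drug_class) if self.assigned else None


def _shape_basis(lib: TemplateLibrary) -> tuple[list[str], np.ndarray]:
    codes = [s.code for s in lib.shapes if not s.is_flat]
    basis = np.stack([lib.shape(c).zscored() for c in codes])
    return codes, basis


def assign_template(profile, lib: TemplateLibrary, r_min: float = 0.85,
                    gene: str = "") -> TemplateAssignment:
    """Assign a single standardized timepoint-mean profile to its best shape.

    The profile is correlated (Pearson) against every non-flat shape; the
    highest r wins, with ties broken by the lowest shape code.  If the best r
    does not exceed ``r_min`` the profile is left unassigned.  Zero-variance
    profiles are routed directly to the flat shape ``00`` (with r recorded as
    1 by convention).
    """
    p = np.asarray(profile, dtype=float)
    if p.shape != (lib.n_timepoints,):
        raise ValueError(
            f"profile has length {p.size}, library expects {lib.n_timepoints}"
        )
    if not np.all(np.isfinite(p)):
        raise ValueError("profile contains non-finite values")
    shapes, rs = assign_profiles(p[None, :], lib, r_min)
    return TemplateAssignment(gene, shapes[0], float(rs[0]))


def assign_profiles(profiles: np.ndarray, lib: TemplateLibrary,
                    r_min: float = 0.85) -> tuple[list[str | None], np.ndarray]:
    """Vectorised template assignment for an (n_genes, T) profile array.

    Returns the per-gene shape code (or None) and the Pearson r of the best
    match (1.0 for zero-variance profiles routed to ``00``).
    """
    P = np.asarray(profiles, dtype=float)
    codes, basis = _shape_basis(lib)
    T = lib.n_timepoints
    sd = P.std(axis=1)
    flat = sd <= 1e-12 * np.maximum(1.0, np.abs(P).max(axis=1, initial=0.0))
    Z = np.zeros_like(P)
    np.divide(P - P.mean(axis=1, keepdims=True), sd[:, None], out=Z, where=~flat[:, None])
    # Pearson r of z-scored vectors is their dot product / T
    R = Z @ basis.T / T
    best_idx = np.argmax(R, axis=1)           # argmax takes the first (lowest code) on ties
    best_r = R[np.arange(len(P)), best_idx]

    out_shapes: list[str | None] = []
    out_r = np.empty(len(P))
    for i in range(len(P)):
        if flat[i]:
            out_shapes.append("00")
            out_r[i] = 1.0
        elif best_r[i] > r_min:
            out_shapes.append(codes[best_idx[i]])
            out_r[i] = best_r[i]
        else:
            out_shapes.append(None)
            out_r[i] = best_r[i]
    return out_shapes, out_r


def classify_drug_effect(rec: AnovaRecord, alpha: float = 0.01) -> str:
    """Classify the overall drug effect of a gene from its ANOVA record.

    ``unchanged`` when the drug main effect is not significant; otherwise
    ``up``/``down`` according to whether the drug-condition grand mean exceeds
    the vehicle grand mean.  An exact tie with a significant drug term is
    degenerate and resolved to ``unchanged`` with a warning.
    """
    if rec.p_drug > alpha:
        return "unchanged"
    veh, drug = rec.cell_means[0].mean(), rec.cell_means[1].mean()
    if drug > veh:
        return "up"
    if drug < veh:
        return "down"
    logger.warning("gene %s: significant drug term but equal grand means; "
                   "classifying as unchanged", rec.gene)
    return "unchanged"


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------

@dataclass
class PatternEnrichment:
    """Binomial over-assignment test result for one pattern."""

    pattern: str
    observed: int
    expected: float
    p: float
    flagged: bool


def template_enrichment(assignments: list[TemplateAssignment], lib: TemplateLibrary,
                        alpha: float = 0.01) -> list[PatternEnrichment]:
    """Test each pattern for holding more assigned genes than chance.

    Under the uniform null every assigned gene falls into each of the
    library's patterns with equal probability; the observed count is tested
    with a one-sided (upper tail) exact binomial test and flagged at
    ``p <= alpha``.
    """
    assigned = [a for a in assignments if a.assigned]
    if not assigned:
        raise ValueError("no assigned genes; enrichment is undefined")
    patterns = lib.patterns
    n = len(assigned)
    p0 = 1.0 / len(patterns)
    counts = {pat: 0 for pat in patterns}
    for a in assigned:
        counts[a.pattern] += 1

    out = []
    for pat in patterns:
        obs = counts[pat]
        p = float(stats.binom.sf(obs - 1, n, p0))  # P(X >= obs)
        out.append(PatternEnrichment(pat, obs, n * p0, p, p <= alpha))
    return out
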