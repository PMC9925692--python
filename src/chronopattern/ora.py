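"""Hypergeometric overrepresentation analysis (ORA) with BH-adjusted FDR.

A query gene list (e.g. the members of a temporal pattern) is tested against
each gene set of a GMT collection: with a universe of N genes of which Tot
belong to the set, and a query of n genes of which Sig belong to the set, the
one-sided p-value is the hypergeometric upper tail P(X >= Sig).  Each row
reports Tot, Sig, the chance expectation Exp = n * Tot / N, the enrichment
Ratio = Sig / Exp, the raw p and the Benjamini-Hochberg FDR across all
tested sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets plus the background universe they are tested against."""

    sets: dict[str, frozenset[str]]
    universe: frozenset[str]

    def restricted(self) -> "GeneSetCollection":
        """Intersect every set with the universe."""
        return GeneSetCollection(
            {name: s & self.universe for name, s in self.sets.items()},
            self.universe,
        )


@dataclass
class OraRecord:
    """One gene set's overrepresentation result (Tot/Sig/Exp/Ratio/p/FDR)."""

    set_id: str
    tot: int
    sig: int
    exp: float
    ratio: float
    p: float
    fdr: float


def sig_exp_ratio(sig: int, exp: float) -> float:
    """Enrichment ratio Sig/Exp (0 when the expectation is 0)."""
    return sig / exp if exp > 0 else 0.0


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_(i) = min_{j >= i} ( m * p_(j) / j ), capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def run_ora(query, collection: GeneSetCollection, min_set: int = 10,
            max_set: int = 2000) -> list[OraRecord]:
    """Overrepresentation analysis of a query list against a collection.

    Query genes outside the universe are logged and dropped; sets whose
    universe-restricted size falls outside ``[min_set, max_set]`` are
    excluded from testing (and from the BH family).
    Records are returned sorted by ascending p.
    """
    if not collection.sets:
        raise ValueError("empty gene-set collection")
    restricted = collection.restricted()
    universe = restricted.universe
    q = set(query)
    dropped = q - universe
    if dropped:
        logger.warning("run_ora: dropping %d query genes outside the universe", len(dropped))
        q &= universe
    if not q:
        raise ValueError("query is empty after restriction to the universe")

    N = len(universe)
    nq = len(q)
    tested = {name: s for name, s in restricted.sets.items()
              if min_set <= len(s) <= max_set}
    if not tested:
        raise ValueError(
            f"no gene sets within size bounds [{min_set}, {max_set}] after restriction"
        )

    names, tots, sigs, ps = [], [], [], []
    for name, s in tested.items():
        tot = len(s)
        sig = len(q & s)
        # upper tail P(X >= sig) for X ~ Hypergeom(N, tot, nq)
        p = float(stats.hypergeom.sf(sig - 1, N, tot, nq))
        names.append(name)
        tots.append(tot)
        sigs.append(sig)
        ps.append(p)

    fdrs = bh_adjust(ps)
    records = []
    for name, tot, sig, p, fdr in zip(names, tots, sigs, ps, fdrs):
        exp = nq * tot / N
        records.append(OraRecord(name, tot, sig, exp, sig_exp_ratio(sig, exp),
                                 p, float(fdr)))
    records.sort(key=lambda r: (r.p, r.set_id))
    return records


def ora_table(records: list[OraRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"set_id": r.set_id, "Tot": r.tot, "Sig": r.sig, "Exp": r.exp,
          "Ratio": r.ratio, "p": r.p, "FDR": r.fdr} for r in records]
    ).set_index("set_id")


# ---------------------------------------------------------------------------
# GMT I/O
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path, universe=None) -> GeneSetCollection:
    """Read a GMT file (set name, description, members; tab-separated).

    When ``universe`` is None it defaults to the union of all set members
    (the convention of common web ORA tools).
    """
    sets: dict[str, frozenset[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line (need name, description, members): {line[:80]!r}")
        name = parts[0]
        if name in sets:
            raise ValueError(f"duplicate gene-set name in GMT: {name!r}")
        sets[name] = frozenset(g for g in parts[2:] if g)
    uni = frozenset(universe) if universe is not None else frozenset().union(*sets.values())
    return GeneSetCollection(sets, uni)


def write_gmt(collection: GeneSetCollection, path: str | Path,
              description: str = "na") -> None:
    lines = []
    for name in sorted(collection.sets):
        members = sorted(collection.sets[name])
        lines.append("\t".join([name, description, *members]))
    Path(path).write_text("\n".join(lines) + "\n")
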