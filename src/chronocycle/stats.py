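"""Lineage-correlation statistics on intermitotic times (IMTs).

The central observable is the cousin–mother inequality (CMI): cousin pairs
showing a larger Pearson IMT correlation than mother–daughter pairs,
quantified per simulation run as ``delta = r_cousin - r_mother_daughter``
and summarised over a run ensemble by its median.

Conventions
-----------
* Only cells with a well-defined IMT enter any statistic: censored cells
  (alive at the stop) are excluded, as are ancestor cells, whose first
  recorded "cycle" starts mid-phase at t = 0 and is therefore truncated.
* Symmetric relations (sister, cousin) include each unordered pair in both
  orders before the correlation is computed; asymmetric relations
  (mother–daughter, grandmother, great-grandmother) put the ancestor in
  slot a.
* Correlations are computed per run, pooling pairs across all ancestors in
  the run; ensembles are across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lineage import LineageTree, SimulationRun

__all__ = [
    "RelationPairSet",
    "CorrelationSummary",
    "CMIStat",
    "RELATIONS",
    "extract_pairs",
    "pearson",
    "correlation_summary",
    "cmi",
    "vertical_correlation",
    "imt_stats",
    "percent_change",
]

RELATIONS = ("sister", "mother_daughter", "cousin", "grandmother",
             "great_grandmother")
_SYMMETRIC = ("sister", "cousin")


@dataclass
class RelationPairSet:
    relation: str
    pairs: np.ndarray          # (n, 2) IMT pairs in hours
    ids: list                  # [(cell_id_a, cell_id_b), ...]

    @property
    def n(self) -> int:
        return len(self.ids)


def _tree_of(obj) -> LineageTree:
    return obj.tree if isinstance(obj, SimulationRun) else obj


def _has_imt(tree: LineageTree, cid: int) -> bool:
    rec = tree.record(cid)
    return (not rec.censored) and rec.full_cycle and rec.IMT is not None


def extract_pairs(tree_or_run, relation: str) -> RelationPairSet:
    """All unique related cell pairs with both IMTs defined.

    sister: same mother; mother_daughter: direct edge; cousin: same
    grandmother, different mothers; grandmother / great_grandmother:
    ancestor exactly 2 / 3 generations up (ancestor in slot a).
    """
    if relation not in RELATIONS:
        raise ValueError(f"unknown relation {relation!r}; one of {RELATIONS}")
    tree = _tree_of(tree_or_run)
    g = tree.graph
    ok = lambda c: _has_imt(tree, c)
    imt = lambda c: tree.record(c).IMT
    ids = []
    if relation == "sister":
        for n in g.nodes:
            ch = sorted(g.successors(n))
            if len(ch) == 2 and ok(ch[0]) and ok(ch[1]):
                ids.append((ch[0], ch[1]))
    elif relation == "mother_daughter":
        for a, b in g.edges:
            if ok(a) and ok(b):
                ids.append((a, b))
    elif relation == "cousin":
        for n in g.nodes:
            ch = sorted(g.successors(n))
            if len(ch) == 2:
                for a in sorted(g.successors(ch[0])):
                    for b in sorted(g.successors(ch[1])):
                        if ok(a) and ok(b):
                            ids.append((a, b))
    else:
        k = 2 if relation == "grandmother" else 3
        for n in g.nodes:
            if not ok(n):
                continue
            anc = n
            for _ in range(k):
                preds = list(g.predecessors(anc))
                anc = preds[0] if preds else None
                if anc is None:
                    break
            if anc is not None and ok(anc):
                ids.append((anc, n))
    pairs = np.array([[imt(a), imt(b)] for a, b in ids], dtype=float)
    pairs = pairs.reshape(-1, 2)
    return RelationPairSet(relation=relation, pairs=pairs, ids=ids)


def pearson(pairset: RelationPairSet) -> float | None:
    """Pearson product-moment correlation of a pair set.

    Symmetric relations are symmetrised (each pair in both orders) first.
    Returns None when fewer than 3 pairs are available or either margin is
    degenerate (zero variance).
    """
    x = pairset.pairs
    if len(x) < 3:
        return None
    if pairset.relation in _SYMMETRIC:
        x = np.vstack([x, x[:, ::-1]])
    a, b = x[:, 0], x[:, 1]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return None
    sa, sb = a.std(), b.std()
    r = float(((a - a.mean()) * (b - b.mean())).mean() / (sa * sb))
    return min(1.0, max(-1.0, r))


@dataclass
class CorrelationSummary:
    """Per-relation Pearson r and pair counts for one run."""

    r: dict            # relation -> float | None
    n_pairs: dict      # relation -> int


def correlation_summary(tree_or_run,
                        relations=("sister", "mother_daughter", "cousin")
                        ) -> CorrelationSummary:
    r, n = {}, {}
    for rel in relations:
        ps = extract_pairs(tree_or_run, rel)
        r[rel] = pearson(ps)
        n[rel] = ps.n
    return CorrelationSummary(r=r, n_pairs=n)


@dataclass
class CMIStat:
    """Cousin-minus-mother-daughter correlation difference over an ensemble."""

    deltas: np.ndarray         # per-run delta values (undefined runs dropped)
    n_undefined: int = 0

    @property
    def median(self) -> float:
        return float(np.median(self.deltas))

    def percent_change_vs(self, reference: "CMIStat") -> float:
        return percent_change(self.deltas, reference.deltas)


def cmi(trees_or_runs) -> CMIStat:
    """Per-run ``r_cousin - r_mother_daughter`` over a run ensemble.

    Runs in which either correlation is undefined (too few pairs or zero
    variance) are dropped and counted in ``n_undefined``.
    """
    if isinstance(trees_or_runs, (LineageTree, SimulationRun)):
        trees_or_runs = [trees_or_runs]
    deltas = []
    undef = 0
    for obj in trees_or_runs:
        rc = pearson(extract_pairs(obj, "cousin"))
        rm = pearson(extract_pairs(obj, "mother_daughter"))
        if rc is None or rm is None:
            undef += 1
        else:
            deltas.append(rc - rm)
    return CMIStat(deltas=np.array(deltas, dtype=float), n_undefined=undef)


def vertical_correlation(tree_or_run, k: int) -> float | None:
    """Pearson r between a cell's IMT and its k-th generation ancestor's.

    ``k = 1`` coincides with the mother–daughter correlation; ``k = 2`` is
    the grandmother correlation, ``k = 3`` great-grandmother.
    """
    if k == 1:
        rel = "mother_daughter"
    elif k == 2:
        rel = "grandmother"
    elif k == 3:
        rel = "great_grandmother"
    else:
        raise ValueError("k must be 1, 2 or 3")
    return pearson(extract_pairs(tree_or_run, rel))


def imt_stats(source, bins=30):
    """Pooled IMT sample moments: mean, SD (n-1), CV and a histogram.

    ``source`` may be a LineageTree / SimulationRun, an iterable of them
    (pooled), or a plain sequence of IMT values.
    """
    if isinstance(source, (LineageTree, SimulationRun)):
        source = [source]
    vals = []
    seq = list(source)
    if seq and isinstance(seq[0], (LineageTree, SimulationRun)):
        for obj in seq:
            tree = _tree_of(obj)
            for cid in tree.graph.nodes:
                if _has_imt(tree, cid):
                    vals.append(tree.record(cid).IMT)
    else:
        vals = [float(v) for v in seq]
    vals = np.asarray(vals, dtype=float)
    if len(vals) < 2:
        raise ValueError("need at least 2 uncensored IMTs")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    hist = np.histogram(vals, bins=bins)
    return {"mean": mean, "sd": sd, "cv": sd / mean, "n": len(vals),
            "histogram": hist}


def percent_change(test, reference) -> float:
    """100 * (median(test) - median(reference)) / median(reference)."""
    test = np.asarray(test, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if len(test) == 0 or len(reference) == 0:
        raise ValueError("both ensembles must be non-empty")
    ref = np.median(reference)
    if ref == 0:
        raise ValueError("reference median is zero; percent change undefined")
    return float(100.0 * (np.median(test) - ref) / ref)
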