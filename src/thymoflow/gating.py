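"""Hierarchical gating of thymic stromal populations.

Encodes the published identification strategy as an executable gate tree:
TECs are pdpn^high/int at any EpCAM level (CD45 is deliberately absent from
the TEC path — it proved dispensable for the strategy), subdivided into
cTEC (CD49f+ CD200-) and mTEC (CD49f int/low CD200+); accessory gates cover
vascular and lymphatic endothelium, fibroblasts, dendritic cells,
macrophages, thymocytes and mature single-positive subsets.

Thresholds are placed automatically per sample: each gate clause is fitted
on the events passing its parent gate, using the valley (minimum) of a
kernel-density estimate between intensity modes, an empirical quantile, or
a fixed value. Panel-calibrated fixed thresholds (midpoints between the
configured phenotype levels on the asinh scale) are available for
reproducible gating across a cohort.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks
from sklearn.base import BaseEstimator

from .errors import (AlignmentError, ConfigError, DataError, GateFitError,
                     PanelError, StateError)
from .io import DEFAULT_COFACTOR, EventTable, PanelConfig, TransformSpec, transform_events

logger = logging.getLogger("thymoflow")

ROOT = "root"

#: Markers the default thymic scheme gates on.
SCHEME_MARKERS = ("CD45", "EpCAM", "pdpn", "CD49f", "CD200", "CD31", "HLA-DR",
                  "CD11c", "CD11b", "CD3", "CD1a", "CD4", "CD8")


# ---------------------------------------------------------------------------
# density estimation and threshold placement

def _density(values, gridsize=1024, min_bw_frac=1.0 / 100.0):
    """Binned kernel density on a regular grid. Returns (grid, density, bw)
    or None for degenerate (constant) input."""
    v = np.asarray(values, dtype=float)
    lo, hi = float(v.min()), float(v.max())
    if hi - lo < 1e-12:
        return None
    sd = v.std()
    q75, q25 = np.percentile(v, [75, 25])
    a = min(sd, (q75 - q25) / 1.34) if q75 > q25 else sd
    bw = 0.9 * a * len(v) ** (-0.2)
    bw = max(bw, (hi - lo) * min_bw_frac)
    counts, edges = np.histogram(v, bins=gridsize, range=(lo, hi))
    width = edges[1] - edges[0]
    dens = gaussian_filter1d(counts.astype(float), sigma=bw / width, mode="constant")
    dens /= len(v) * width
    grid = 0.5 * (edges[:-1] + edges[1:])
    return grid, dens, bw


def density_modes(values, *, min_peak_events=15, rel_prominence=0.5, gridsize=1024):
    """Locate intensity modes as peaks of the binned KDE.

    A peak must (a) carry the density equivalent of at least
    ``min_peak_events`` events within one bandwidth, which suppresses
    stray-tail wiggles while keeping sub-percent subpopulations detectable,
    and (b) have prominence of at least ``rel_prominence`` of its own
    height, so histogram jitter on a mode's shoulder does not split it.
    Returns (grid, density, peak_indices, peak_heights).
    """
    est = _density(values, gridsize=gridsize)
    if est is None:
        return None
    grid, dens, bw = est
    floor = min_peak_events / (len(values) * bw * math.sqrt(2.0 * math.pi))
    padded = np.concatenate([[0.0], dens, [0.0]])
    peaks, props = find_peaks(padded, height=floor, prominence=floor / 2.0)
    heights = props["peak_heights"]
    keep = props["prominences"] >= rel_prominence * heights
    return grid, dens, peaks[keep] - 1, heights[keep]


def _valleys(values, **kwargs):
    """Inter-mode valley locations (sorted left to right)."""
    modes = density_modes(values, **kwargs)
    if modes is None:
        return []
    grid, dens, peaks, _ = modes
    cuts = []
    for i, j in zip(peaks[:-1], peaks[1:]):
        k = int(np.argmin(dens[i:j + 1])) + i
        cuts.append(float(grid[k]))
    return cuts


def place_threshold(values, method) -> float:
    """Place a single threshold on 1-D transformed intensities.

    ``method`` is ``"valley"`` (KDE minimum between the two largest density
    modes; needs >= 50 values; unimodal data falls back to quantile(0.99)
    with a warning), ``("quantile", q)`` or ``("fixed", v)``. String forms
    ``"quantile:0.5"`` and ``"fixed:1.7"`` are accepted.
    """
    kind, arg = _parse_method(method)
    if kind == "fixed":
        return float(arg)
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise DataError("cannot place a threshold on empty data")
    if kind == "quantile":
        return float(np.quantile(v, arg))
    if kind == "valley":
        if v.size < 50:
            raise DataError("valley placement needs at least 50 values")
        modes = density_modes(v)
        peaks = modes[2] if modes is not None else np.array([], dtype=int)
        if modes is None or len(peaks) < 2:
            logger.warning("unimodal data: valley falls back to quantile(0.99)")
            return float(np.quantile(v, 0.99))
        grid, dens, peaks, heights = modes
        top_two = np.sort(peaks[np.argsort(heights)[-2:]])
        i, j = int(top_two[0]), int(top_two[1])
        k = int(np.argmin(dens[i:j + 1])) + i
        return float(grid[k])
    raise ConfigError(f"unknown threshold method {method!r}")


def _parse_method(method):
    if isinstance(method, (tuple, list)):
        kind, arg = method
        return str(kind), arg
    if isinstance(method, str):
        if ":" in method:
            kind, arg = method.split(":", 1)
            return kind, (int(arg) if kind == "valley" else float(arg))
        return method, 1
    raise ConfigError(f"cannot parse threshold method {method!r}")


def _method_to_str(method):
    kind, arg = _parse_method(method)
    if kind == "valley" and arg == 1:
        return "valley"
    return f"{kind}:{arg}"


# ---------------------------------------------------------------------------
# gate tree

@dataclass
class Clause:
    """One axis-aligned condition: marker OP threshold.

    ``op`` is one of >, >=, <, <=, between. For ``between`` the method and
    threshold are (low, high) pairs; membership is ``lo <= x < hi``.
    """

    marker: str
    op: str
    method: object = "valley"
    threshold: object = None

    def evaluate(self, x):
        t = self.threshold
        if t is None:
            raise GateFitError(f"clause on {self.marker!r} has no fitted threshold")
        if self.op == ">":
            return x > t
        if self.op == ">=":
            return x >= t
        if self.op == "<":
            return x < t
        if self.op == "<=":
            return x <= t
        if self.op == "between":
            lo, hi = t
            return (x >= lo) & (x < hi)
        raise ConfigError(f"unknown operator {self.op!r}")


@dataclass
class GateNode:
    name: str
    parent: str
    clauses: list
    mode: str = "all"  # "all" = AND of clauses, "any" = OR


@dataclass
class GatingTree:
    """Rooted tree of gate nodes; the root scope is every event."""

    nodes: dict = field(default_factory=dict)
    fitted: bool = False

    def add(self, node: GateNode):
        if node.name in self.nodes or node.name == ROOT:
            raise ConfigError(f"duplicate gate node {node.name!r}")
        if node.parent != ROOT and node.parent not in self.nodes:
            raise ConfigError(f"parent {node.parent!r} of {node.name!r} not defined yet")
        self.nodes[node.name] = node
        return self

    def children(self, name):
        return [n for n in self.nodes.values() if n.parent == name]

    def walk(self):
        """Nodes in depth-first order (parents before children)."""
        out = []

        def rec(parent):
            for node in self.children(parent):
                out.append(node)
                rec(node.name)

        rec(ROOT)
        if len(out) != len(self.nodes):  # unreachable nodes => cycle/orphan
            raise ConfigError("gating tree contains unreachable nodes")
        return out

    def path(self, name):
        parts = []
        while name != ROOT:
            parts.append(name)
            name = self.nodes[name].parent
        return "/".join(reversed(parts))

    def markers(self):
        return sorted({c.marker for n in self.nodes.values() for c in n.clauses})

    # -- serialization ------------------------------------------------------
    def to_dict(self):
        def clause_doc(c):
            doc = {"marker": c.marker, "op": c.op}
            if c.op == "between":
                doc["method"] = [_method_to_str(m) for m in c.method]
                doc["threshold"] = list(c.threshold) if c.threshold is not None else None
            else:
                doc["method"] = _method_to_str(c.method)
                doc["threshold"] = c.threshold
            return doc

        return {
            "fitted": self.fitted,
            "nodes": [
                {"name": n.name, "parent": n.parent, "mode": n.mode,
                 "clauses": [clause_doc(c) for c in n.clauses]}
                for n in self.walk()
            ],
        }

    @classmethod
    def from_dict(cls, doc):
        tree = cls(fitted=bool(doc.get("fitted", False)))
        for nd in doc["nodes"]:
            clauses = []
            for cd in nd["clauses"]:
                method = cd.get("method", "valley")
                threshold = cd.get("threshold")
                if cd["op"] == "between":
                    method = tuple(method)
                    threshold = tuple(threshold) if threshold is not None else None
                clauses.append(Clause(cd["marker"], cd["op"], method, threshold))
            tree.add(GateNode(nd["name"], nd["parent"], clauses, nd.get("mode", "all")))
        return tree

    def to_yaml(self, path=None):
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source):
        try:
            with open(source) as fh:
                doc = yaml.safe_load(fh)
        except (OSError, TypeError):
            doc = yaml.safe_load(source)
        return cls.from_dict(doc)


def build_thymic_gating_tree(panel: PanelConfig | None = None, overrides=None) -> GatingTree:
    """The default thymic gate tree, unfitted.

    TEC admits all EpCAM levels when pdpn is int/high (lower pdpn cut at the
    rank-2 inter-mode valley, i.e. above the fibroblast pdpn mode), with the
    CD31+ lymphatic branch excluded upstream. CD45 is omitted from the TEC
    path but retained for the accessory gates. ``overrides`` maps node name
    to ``{marker: value-or-method}`` replacing that clause's placement.
    """
    if panel is not None:
        available = {panel.resolve(m) for m in panel.required_markers}
        missing = [m for m in SCHEME_MARKERS if m not in available]
        if missing:
            raise PanelError(f"panel cannot resolve scheme markers: {missing}")

    V1, V2 = ("valley", 1), ("valley", 2)
    tree = GatingTree()
    tree.add(GateNode("TEC", ROOT, [Clause("pdpn", ">=", V2), Clause("CD31", "<", V1)]))
    tree.add(GateNode("cTEC", "TEC", [Clause("CD49f", ">=", V1), Clause("CD200", "<", V1)]))
    tree.add(GateNode("mTEC", "TEC", [Clause("CD49f", "<", V1), Clause("CD200", ">=", V1)]))
    tree.add(GateNode("EC", ROOT, [Clause("CD45", "<", V1), Clause("CD31", ">=", V1),
                                   Clause("pdpn", "<", V1)]))
    tree.add(GateNode("LEC", ROOT, [Clause("CD45", "<", V1), Clause("CD31", ">=", V1),
                                    Clause("pdpn", ">=", V1), Clause("CD49f", ">=", V1),
                                    Clause("CD200", ">=", V1)]))
    tree.add(GateNode("FB", ROOT, [Clause("CD45", "<", V1), Clause("EpCAM", "<", V1),
                                   Clause("HLA-DR", "<", V1),
                                   Clause("pdpn", "between", (V1, V2))]))
    tree.add(GateNode("DC", ROOT, [Clause("CD45", ">=", V1), Clause("HLA-DR", ">=", V1),
                                   Clause("CD11c", ">=", V1), Clause("CD11b", ">=", V1)]))
    tree.add(GateNode("MP", ROOT, [Clause("CD45", ">=", V1), Clause("HLA-DR", ">=", V1),
                                   Clause("CD11c", "<", V1), Clause("CD11b", ">=", V1)]))
    tree.add(GateNode("thymocyte", ROOT, [Clause("CD3", ">=", V1), Clause("CD1a", ">=", V1)],
                      mode="any"))
    tree.add(GateNode("matureSP", "thymocyte", [Clause("CD3", ">=", V1),
                                                Clause("CD1a", "<", V1)]))
    tree.add(GateNode("CD4SP", "matureSP", [Clause("CD4", ">=", V1), Clause("CD8", "<", V1)]))
    tree.add(GateNode("CD8SP", "matureSP", [Clause("CD8", ">=", V1), Clause("CD4", "<", V1)]))

    if overrides:
        _apply_overrides(tree, overrides)
    return tree


def _as_method(value):
    if isinstance(value, (int, float)):
        return ("fixed", float(value))
    return value


def _apply_overrides(tree: GatingTree, overrides):
    for node_name, clause_overrides in overrides.items():
        if node_name not in tree.nodes:
            raise ConfigError(f"override names unknown gate node {node_name!r}")
        node = tree.nodes[node_name]
        for marker, value in clause_overrides.items():
            hit = [c for c in node.clauses if c.marker == marker]
            if not hit:
                raise ConfigError(f"node {node_name!r} has no clause on {marker!r}")
            for clause in hit:
                if clause.op == "between":
                    lo, hi = value
                    clause.method = (_as_method(lo), _as_method(hi))
                else:
                    clause.method = _as_method(value)


def default_fixed_thresholds(phenotypes=None, cofactor: float = DEFAULT_COFACTOR):
    """Panel-calibrated fixed thresholds: midpoints between the configured
    phenotype levels on the asinh scale. Usable as tree overrides for
    reproducible gating across a cohort."""
    from .simulate import load_phenotypes

    pheno = phenotypes or load_phenotypes()
    a = {lvl: math.asinh(v / cofactor) for lvl, v in pheno["levels"].items()}
    mid = lambda l1, l2: 0.5 * (a[l1] + a[l2])
    pos = mid("neg", "hi")          # generic on/off cut for bimodal markers
    pdpn_lo = mid("neg", "lo")      # below the fibroblast pdpn mode
    pdpn_tec = mid("lo", "int")     # between the FB and TEC pdpn modes
    return {
        "TEC": {"pdpn": pdpn_tec, "CD31": pos},
        "cTEC": {"CD49f": mid("lo", "hi"), "CD200": pos},
        "mTEC": {"CD49f": mid("lo", "hi"), "CD200": pos},
        "EC": {"CD45": pos, "CD31": pos, "pdpn": pdpn_lo},
        "LEC": {"CD45": pos, "CD31": pos, "pdpn": pdpn_lo,
                "CD49f": mid("lo", "hi"), "CD200": pos},
        "FB": {"CD45": pos, "EpCAM": mid("neg", "lo"), "HLA-DR": pos,
               "pdpn": (pdpn_lo, pdpn_tec)},
        "DC": {"CD45": pos, "HLA-DR": pos, "CD11c": pos, "CD11b": pos},
        "MP": {"CD45": pos, "HLA-DR": pos, "CD11c": pos, "CD11b": pos},
        "thymocyte": {"CD3": mid("neg", "int"), "CD1a": mid("neg", "lo")},
        "matureSP": {"CD3": mid("int", "hi"), "CD1a": mid("lo", "hi")},
        "CD4SP": {"CD4": mid("int", "hi"), "CD8": mid("int", "hi")},
        "CD8SP": {"CD8": mid("int", "hi"), "CD4": mid("int", "hi")},
    }


# ---------------------------------------------------------------------------
# fitting and application

def _fit_value(values, method, node_name, marker):
    kind, arg = _parse_method(method)
    if kind == "fixed":
        return float(arg)
    if values.size == 0:
        raise GateFitError(f"node {node_name!r}: no events in scope to fit {marker!r}")
    if kind == "quantile":
        return float(np.quantile(values, arg))
    if kind == "valley":
        if values.size < 50:
            raise GateFitError(
                f"node {node_name!r}: too few events ({values.size}) to fit "
                f"a valley threshold on {marker!r}")
        cuts = _valleys(values)
        rank = int(arg)
        if len(cuts) < rank:
            logger.warning("node %r: fewer than %d density valleys on %r; "
                           "falling back to quantile(0.99)", node_name, rank, marker)
            return float(np.quantile(values, 0.99))
        return cuts[rank - 1]
    raise ConfigError(f"unknown threshold method {method!r}")


def fit_tree(tree: GatingTree, table: EventTable) -> GatingTree:
    """Fit every clause threshold on the events in its parent's scope.

    Returns a fitted copy; the input tree is unmodified.
    """
    if table.scale_state != "transformed":
        raise StateError("fit gating thresholds on transformed intensities")
    fitted = GatingTree.from_dict(tree.to_dict())
    masks = {ROOT: np.ones(table.n_events, dtype=bool)}
    for node in fitted.walk():
        scope = masks[node.parent]
        clause_masks = []
        for clause in node.clauses:
            x = table.values(clause.marker)
            xs = x[scope]
            if clause.op == "between":
                lo = _fit_value(xs, clause.method[0], node.name, clause.marker)
                hi = _fit_value(xs, clause.method[1], node.name, clause.marker)
                if not lo < hi:
                    raise GateFitError(
                        f"node {node.name!r}: between-clause on {clause.marker!r} "
                        f"fitted lo={lo:.3g} >= hi={hi:.3g}")
                clause.threshold = (lo, hi)
            else:
                clause.threshold = _fit_value(xs, clause.method, node.name, clause.marker)
            clause_masks.append(clause.evaluate(x))
        combined = (np.logical_and.reduce(clause_masks) if node.mode == "all"
                    else np.logical_or.reduce(clause_masks))
        masks[node.name] = scope & combined
    fitted.fitted = True
    return fitted


@dataclass
class GateAssignment:
    """Per-event deepest gate label ('ungated' when no gate matches)."""

    labels: np.ndarray
    tree: GatingTree

    def path(self, label):
        return self.tree.path(label) if label in self.tree.nodes else label


@dataclass
class PopulationStats:
    """Per-node event counts and frequencies (of parent and of total)."""

    table: pd.DataFrame
    total: int
    n_ungated: int
    empty: bool = False

    def count(self, population):
        return int(self.table.loc[population, "count"])

    def freq_of_total(self, population):
        return float(self.table.loc[population, "freq_of_total"])


def _node_masks(table: EventTable, tree: GatingTree):
    masks = {ROOT: np.ones(table.n_events, dtype=bool)}
    cache = {}  # identical clauses recur across sibling gates
    for node in tree.walk():
        clause_masks = []
        for c in node.clauses:
            key = (c.marker, c.op, repr(c.threshold))
            if key not in cache:
                cache[key] = c.evaluate(table.values(c.marker))
            clause_masks.append(cache[key])
        combined = (np.logical_and.reduce(clause_masks) if node.mode == "all"
                    else np.logical_or.reduce(clause_masks))
        masks[node.name] = masks[node.parent] & combined
    return masks


def apply_gating(table: EventTable, tree: GatingTree):
    """Gate a transformed event table; returns (GateAssignment, PopulationStats).

    An unfitted tree is fitted on this table first. Events are labeled with
    the deepest gate whose full ancestor path they satisfy; an event caught
    by two same-depth sibling gates keeps the first-declared one.
    """
    if table.scale_state != "transformed":
        raise StateError("gating operates on transformed intensities")
    if table.n_events == 0:
        rows = [{"population": n.name, "parent": n.parent, "count": 0,
                 "freq_of_parent": 0.0, "freq_of_total": 0.0}
                for n in tree.walk()]
        stats = PopulationStats(pd.DataFrame(rows).set_index("population", drop=False),
                                total=0, n_ungated=0, empty=True)
        return GateAssignment(np.array([], dtype=object), tree), stats

    if not tree.fitted:
        tree = fit_tree(tree, table)
    masks = _node_masks(table, tree)

    walk = tree.walk()
    code = np.zeros(table.n_events, dtype=np.int16)  # 0 = ungated
    depth = np.zeros(table.n_events, dtype=np.int16)
    node_depth = {ROOT: 0}
    for k, node in enumerate(walk, start=1):
        node_depth[node.name] = node_depth[node.parent] + 1
        take = masks[node.name] & (node_depth[node.name] > depth)
        code[take] = k
        depth[take] = node_depth[node.name]
    names = np.array(["ungated"] + [n.name for n in walk], dtype=object)
    labels = names[code]

    total = table.n_events
    rows = []
    for node in tree.walk():
        count = int(masks[node.name].sum())
        parent_count = int(masks[node.parent].sum())
        rows.append({
            "population": node.name, "parent": node.parent, "count": count,
            "freq_of_parent": count / parent_count if parent_count else 0.0,
            "freq_of_total": count / total,
        })
    stats = PopulationStats(pd.DataFrame(rows).set_index("population", drop=False),
                            total=total, n_ungated=int((labels == "ungated").sum()))
    return GateAssignment(labels, tree), stats


# ---------------------------------------------------------------------------
# evaluation

@dataclass
class GateEvalReport:
    per_population: pd.DataFrame  # population, support, precision, recall, f1
    confusion: pd.DataFrame       # truth x assigned counts

    def f1(self, population):
        return float(self.per_population.loc[population, "f1"])


def thymic_label_map():
    """Truth-population -> expected-gate-node map from the phenotype config."""
    from .simulate import load_phenotypes

    return dict(load_phenotypes()["expected_gate"])


def evaluate_gating(assignment, truth_labels, label_map=None) -> GateEvalReport:
    """Precision/recall/F1 per population from the assignment-vs-truth
    confusion counts. Truth labels are first mapped to the gate node they
    should land in (default: identity). Populations with zero truth support
    get recall (and F1) as NaN, not 0.
    """
    assigned = assignment.labels if isinstance(assignment, GateAssignment) else np.asarray(assignment)
    truth = np.asarray(truth_labels)
    if len(assigned) != len(truth):
        raise AlignmentError(
            f"assignment has {len(assigned)} events but truth has {len(truth)}")
    label_map = label_map or {}
    truth = np.array([label_map.get(t, t) for t in truth], dtype=object)

    classes = sorted(set(truth) | set(assigned))
    confusion = pd.crosstab(pd.Series(truth, name="truth"),
                            pd.Series(assigned, name="assigned"))
    confusion = confusion.reindex(index=classes, columns=classes, fill_value=0)

    rows = []
    for cls in classes:
        tp = int(confusion.loc[cls, cls])
        fp = int(confusion[cls].sum()) - tp
        fn = int(confusion.loc[cls].sum()) - tp
        support = tp + fn
        precision = tp / (tp + fp) if (tp + fp) else np.nan
        recall = tp / support if support else np.nan
        if np.isnan(precision) or np.isnan(recall) or (precision + recall) == 0:
            f1 = np.nan if (np.isnan(recall) or np.isnan(precision)) else 0.0
        else:
            f1 = 2 * precision * recall / (precision + recall)
        rows.append({"population": cls, "support": support,
                     "precision": precision, "recall": recall, "f1": f1})
    report = pd.DataFrame(rows).set_index("population", drop=False)
    return GateEvalReport(per_population=report, confusion=confusion)


# ---------------------------------------------------------------------------
# sklearn facade

class GatingClassifier(BaseEstimator):
    """Hierarchical gating as a fit/predict estimator.

    ``fit`` transforms raw intensities to the asinh scale and places every
    gate threshold on the fitted sample (or applies fixed panel-calibrated
    cuts); ``predict`` returns the deepest gate label per event. Accepts an
    :class:`EventTable` or a DataFrame of raw intensities with marker
    columns.
    """

    def __init__(self, tree=None, overrides=None, fixed=False,
                 cofactor: float = DEFAULT_COFACTOR):
        self.tree = tree
        self.overrides = overrides
        self.fixed = fixed
        self.cofactor = cofactor

    def _as_table(self, X) -> EventTable:
        if isinstance(X, EventTable):
            table = X
        else:
            from .io import ChannelMeta

            df = pd.DataFrame(X)
            channels = [ChannelMeta(str(c)) for c in df.columns]
            table = EventTable("X", df.to_numpy(dtype=float), channels, "raw", None)
        if table.scale_state == "raw":
            table = transform_events(table, TransformSpec("asinh", self.cofactor))
        return table

    def _build_tree(self) -> GatingTree:
        if self.tree is not None:
            return GatingTree.from_dict(self.tree.to_dict())
        overrides = dict(self.overrides or {})
        if self.fixed:
            base = default_fixed_thresholds(cofactor=self.cofactor)
            for node, cuts in base.items():
                merged = dict(cuts)
                merged.update(overrides.get(node, {}))
                overrides[node] = merged
        return build_thymic_gating_tree(overrides=overrides or None)

    def fit(self, X, y=None):
        table = self._as_table(X)
        tree = self._build_tree()
        self.tree_ = tree if tree.fitted else fit_tree(tree, table)
        self.classes_ = np.array([n.name for n in self.tree_.walk()] + ["ungated"])
        return self

    def predict(self, X):
        if not hasattr(self, "tree_"):
            raise StateError("GatingClassifier is not fitted")
        table = self._as_table(X)
        assignment, _ = apply_gating(table, self.tree_)
        return assignment.labels

    def fit_predict(self, X, y=None):
        return self.fit(X).predict(X)

    def stats(self, X) -> PopulationStats:
        if not hasattr(self, "tree_"):
            raise StateError("GatingClassifier is not fitted")
        _, stats = apply_gating(self._as_table(X), self.tree_)
        return stats
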