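"""Detection of co-abundance response guilds and the co-response network.

The algorithm: screen OTUs whose CLR shifts respond to treatment
(one-sample signed-rank p < 0.1), correlate shifts between OTUs across
subjects (Spearman), convert to a 1 - rho distance, cluster with complete
linkage, and cut the tree top-down wherever PERMANOVA separates the two
child clusters (p < 0.05). Retained edges of the companion network require
|rho| >= 0.5 and permutation-FDR q < 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy

from microguild.data_model import AbundanceTable, MetadataTable
from microguild.stats import ClrMatrix, DistanceMatrix, bh_fdr, permanova

GUILD_PREFIX = "guild"


class ShiftMatrix:
    """Subjects x OTUs matrix of CLR differences between two timepoints."""

    def __init__(
        self,
        subject_ids: list[str],
        otu_ids: list[str],
        values: np.ndarray,
        from_tp: str = "BL",
        to_tp: str = "W6",
    ):
        values = np.asarray(values, dtype=float)
        if values.shape != (len(subject_ids), len(otu_ids)):
            raise ValueError("shape mismatch")
        if not np.all(np.isfinite(values)):
            raise ValueError("shift matrix contains non-finite values")
        self.subject_ids = list(subject_ids)
        self.otu_ids = list(otu_ids)
        self.values = values
        self.from_tp = from_tp
        self.to_tp = to_tp

    def column(self, otu_id: str) -> np.ndarray:
        return self.values[:, self.otu_ids.index(otu_id)]

    def select_otus(self, otu_ids: list[str]) -> "ShiftMatrix":
        idx = [self.otu_ids.index(o) for o in otu_ids]
        return ShiftMatrix(
            self.subject_ids, otu_ids, self.values[:, idx], self.from_tp, self.to_tp
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.subject_ids, columns=self.otu_ids)


def compute_shift_matrix(
    clr: ClrMatrix, meta: MetadataTable, from_tp: str, to_tp: str,
    arm: str | None = None,
) -> ShiftMatrix:
    """Per-subject CLR(to_tp) - CLR(from_tp) over all OTUs.

    Subjects missing either timepoint are excluded with a warning. With
    ``arm`` given, only subjects in that treatment arm are considered.
    """
    subjects = meta.subjects()
    if arm is not None:
        subjects = [s for s in subjects if meta.arm_of(s) == arm]
    rows, kept, dropped = [], [], []
    for subject in subjects:
        s_from = meta.sample_for(subject, from_tp)
        s_to = meta.sample_for(subject, to_tp)
        if (
            s_from is None or s_to is None
            or s_from not in clr.sample_ids or s_to not in clr.sample_ids
        ):
            dropped.append(subject)
            continue
        rows.append(clr.row(s_to) - clr.row(s_from))
        kept.append(subject)
    if dropped:
        warnings.warn(
            f"{len(dropped)} subject(s) missing a timepoint excluded: {dropped}",
            stacklevel=2,
        )
    if not kept:
        raise ValueError(f"no subject has both timepoints {from_tp!r} and {to_tp!r}")
    return ShiftMatrix(kept, clr.otu_ids, np.vstack(rows), from_tp, to_tp)


def screen_responsive_otus(
    shifts: ShiftMatrix, alpha_screen: float = 0.1
) -> list[str]:
    """OTUs whose shifts differ from zero (signed-rank, unadjusted p < alpha)."""
    if len(shifts.subject_ids) < 5:
        raise ValueError("need at least five subjects for the screen")
    kept = []
    for j, otu in enumerate(shifts.otu_ids):
        col = shifts.values[:, j]
        if np.all(col == 0):
            continue
        _, p = sps.wilcoxon(col, alternative="two-sided")
        if p < alpha_screen:
            kept.append(otu)
    if not kept:
        warnings.warn("no OTU passed the responsiveness screen", stacklevel=2)
    return kept


def shift_correlation_distance(
    shifts: ShiftMatrix, otus: list[str] | None = None
) -> tuple[pd.DataFrame, DistanceMatrix]:
    """Spearman correlation of shifts between OTUs and the 1 - rho distance.

    Ties receive average ranks. Raises if any OTU's shift vector is constant
    (its correlation is undefined).
    """
    sub = shifts if otus is None else shifts.select_otus(list(otus))
    n, k = sub.values.shape
    if n < 3:
        raise ValueError("need at least three subjects")
    if k < 2:
        raise ValueError("need at least two OTUs")
    for j, otu in enumerate(sub.otu_ids):
        if np.ptp(sub.values[:, j]) == 0:
            raise ValueError(f"OTU {otu!r} has a constant shift vector")
    rho = sps.spearmanr(sub.values).statistic
    rho = np.atleast_2d(rho)
    if rho.shape == (1, 1):  # spearmanr collapses the 2-column case
        r = float(sps.spearmanr(sub.values[:, 0], sub.values[:, 1]).statistic)
        rho = np.array([[1.0, r], [r, 1.0]])
    dist = 1.0 - rho
    np.fill_diagonal(dist, 0.0)
    corr = pd.DataFrame(rho, index=sub.otu_ids, columns=sub.otu_ids)
    return corr, DistanceMatrix(sub.otu_ids, dist)


class Dendrogram:
    """Complete-linkage merge tree over OTU ids with cophenetic heights."""

    def __init__(self, ids: list[str], linkage_matrix: np.ndarray):
        self.ids = list(ids)
        self.linkage = np.asarray(linkage_matrix, dtype=float)
        heights = self.linkage[:, 2]
        if np.any(np.diff(heights) < -1e-12):
            raise ValueError("merge heights must be non-decreasing")

    def cophenetic(self) -> DistanceMatrix:
        from scipy.spatial.distance import squareform

        coph = hierarchy.cophenet(self.linkage)
        return DistanceMatrix(self.ids, squareform(coph))

    def to_newick(self) -> str:
        """Newick string with OTU ids as leaves and merge heights encoded as
        branch lengths (child branch = parent height - child height)."""
        tree = hierarchy.to_tree(self.linkage)

        def render(node, parent_height: float) -> str:
            length = parent_height - (0.0 if node.is_leaf() else node.dist)
            if node.is_leaf():
                return f"{self.ids[node.id]}:{parent_height:.6g}"
            left = render(node.left, node.dist)
            right = render(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return render(tree, tree.dist).rsplit(":", 1)[0] + ";"


def complete_linkage_tree(d: DistanceMatrix) -> Dendrogram:
    """Agglomerative complete-linkage tree over a distance matrix.

    Leaves are ordered lexicographically by id before linkage so that ties
    break deterministically regardless of input order.
    """
    if len(d.ids) < 2:
        raise ValueError("need at least two leaves")
    order = sorted(range(len(d.ids)), key=lambda i: d.ids[i])
    ids = [d.ids[i] for i in order]
    from scipy.spatial.distance import squareform

    condensed = squareform(d.values[np.ix_(order, order)], checks=False)
    return Dendrogram(ids, hierarchy.linkage(condensed, method="complete"))


@dataclass(frozen=True)
class SplitRecord:
    node_id: int
    left_size: int
    right_size: int
    pseudo_f: float
    p: float
    accepted: bool


@dataclass
class GuildAssignment:
    """Partition of screened OTUs into co-response guilds.

    ``labels`` maps otu_id -> guild label; guilds are numbered by descending
    mean member shift (guild1 has the largest mean increase). ``split_log``
    records every PERMANOVA performed while cutting the tree.
    """

    labels: dict[str, str]
    split_log: list[SplitRecord] = field(default_factory=list)

    def members(self, label: str) -> list[str]:
        return [o for o, lab in self.labels.items() if lab == label]

    def guild_labels(self) -> list[str]:
        seen: list[str] = []
        for lab in self.labels.values():
            if lab not in seen:
                seen.append(lab)
        return sorted(seen, key=lambda s: int(s[len(GUILD_PREFIX):]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"otu_id": list(self.labels), "guild": list(self.labels.values())}
        ).set_index("otu_id")


def _pseudo_f(d2: np.ndarray, labels: np.ndarray) -> float:
    """One-way PERMANOVA pseudo-F for a squared-distance matrix."""
    n = len(labels)
    groups = np.unique(labels)
    g = len(groups)
    ss_total = float(d2[np.triu_indices(n, 1)].sum()) / n
    ssw = 0.0
    for lab in groups:
        idx = np.flatnonzero(labels == lab)
        if idx.size > 1:
            sub = d2[np.ix_(idx, idx)]
            ssw += float(sub[np.triu_indices(idx.size, 1)].sum()) / idx.size
    if ssw <= 0:
        return np.inf
    return ((ss_total - ssw) / (g - 1)) / (ssw / (n - g))


def _spearman_d2(values: np.ndarray) -> np.ndarray:
    """Squared 1 - Spearman-rho distances between the columns of ``values``."""
    ranks = sps.rankdata(values, axis=0)
    z = ranks - ranks.mean(axis=0)
    norms = np.sqrt((z**2).sum(axis=0))
    norms[norms == 0] = np.inf
    z = z / norms
    d = 1.0 - z.T @ z
    np.fill_diagonal(d, 0.0)
    return np.clip((d + d.T) / 2.0, 0.0, None) ** 2


def _best_split_f(d2: np.ndarray) -> float:
    """Pseudo-F of the complete-linkage root split of a squared-distance matrix."""
    from scipy.spatial.distance import squareform

    z = hierarchy.linkage(squareform(np.sqrt(d2), checks=False), method="complete")
    root = hierarchy.to_tree(z)
    labels = np.zeros(d2.shape[0], dtype=int)
    labels[root.right.pre_order(lambda x: x.id)] = 1
    return _pseudo_f(d2, labels)


def cut_tree_by_permanova(
    tree: Dendrogram,
    d: DistanceMatrix,
    shifts: ShiftMatrix | None = None,
    alpha_split: float = 0.05,
    n_perm: int = 999,
    seed: int = 0,
    split_test: str = "auto",
) -> GuildAssignment:
    """Cut a dendrogram into guilds by recursive top-down PERMANOVA.

    At each internal node the two child clusters are compared by a PERMANOVA
    pseudo-F on the node's OTU-level distance submatrix. A significant split
    (p < alpha_split) is accepted and recursion continues into children with
    two or more members; a non-significant split stops and the node's leaves
    become one guild. A 1-vs-1 node is degenerate and is never tested: its
    two leaves form one guild. Guilds are numbered by descending mean member
    shift when ``shifts`` is given, else by first appearance.

    ``split_test`` chooses the permutation null:

    - ``"row_shuffle"`` (default whenever ``shifts`` is given): under the
      null the node's OTUs are exchangeable given per-subject effects, so
      each subject's shift values are permuted independently across the
      node's OTUs; every permuted dataset is re-clustered and its best-split
      pseudo-F recorded. This accounts for the fact that the tested split
      was itself selected by the clustering, which makes the plain
      label-permutation test strongly anti-conservative.
    - ``"label"``: plain PERMANOVA label permutation of the fixed split.
    """
    if set(tree.ids) != set(d.ids):
        raise ValueError("tree and distance matrix must cover the same ids")
    if split_test not in ("auto", "row_shuffle", "label"):
        raise ValueError(f"unknown split_test {split_test!r}")
    if split_test == "auto":
        split_test = "row_shuffle" if shifts is not None else "label"
    if split_test == "row_shuffle" and shifts is None:
        raise ValueError("row_shuffle split test requires the shift matrix")
    root = hierarchy.to_tree(tree.linkage)
    log: list[SplitRecord] = []
    groups: list[list[str]] = []
    rng = np.random.default_rng(seed)

    def leaf_ids(node) -> list[str]:
        return [tree.ids[i] for i in node.pre_order(lambda x: x.id)]

    def row_shuffle_p(ids: list[str], labels: np.ndarray) -> tuple[float, float]:
        node_vals = shifts.select_otus(ids).values
        d2 = d.submatrix(ids).values ** 2
        f_obs = _pseudo_f(d2, labels)
        exceed = 0
        for _ in range(n_perm):
            order = np.argsort(rng.random(node_vals.shape), axis=1)
            null_vals = np.take_along_axis(node_vals, order, axis=1)
            if _best_split_f(_spearman_d2(null_vals)) >= f_obs - 1e-12:
                exceed += 1
        return f_obs, (1 + exceed) / (n_perm + 1)

    def recurse(node) -> None:
        if node.is_leaf():
            groups.append([tree.ids[node.id]])
            return
        left, right = leaf_ids(node.left), leaf_ids(node.right)
        if len(left) == 1 and len(right) == 1:
            groups.append(left + right)
            return
        ids = left + right
        labels = np.array([0] * len(left) + [1] * len(right))
        if split_test == "row_shuffle":
            f_obs, p = row_shuffle_p(ids, labels)
        else:
            res = permanova(
                d.submatrix(ids), labels, n_perm=n_perm,
                seed=int(rng.integers(0, 2**32)),
            )
            f_obs, p = res.pseudo_f, res.p
        accepted = p < alpha_split
        log.append(
            SplitRecord(node.id, len(left), len(right), float(f_obs), float(p),
                        accepted)
        )
        if accepted:
            recurse(node.left)
            recurse(node.right)
        else:
            groups.append(ids)

    recurse(root)

    if shifts is not None:
        mean_shift = {
            o: float(np.mean(shifts.column(o)))
            for group in groups
            for o in group
        }
        groups = sorted(
            groups, key=lambda grp: -np.mean([mean_shift[o] for o in grp])
        )
    labels: dict[str, str] = {}
    for i, group in enumerate(groups, start=1):
        for otu in group:
            labels[otu] = f"{GUILD_PREFIX}{i}"
    return GuildAssignment(labels=labels, split_log=log)


def guild_abundance_table(
    table: AbundanceTable, assignment: GuildAssignment
) -> AbundanceTable:
    """Relative abundance of each guild: sum of member OTU abundances.

    Unassigned OTUs are ignored. The output is left in ``relative`` mode
    semantics but rows are not re-closed (guild totals are bounded by one).
    """
    if table.mode != "relative":
        raise ValueError("guild abundances require a relative-mode table")
    labels = assignment.guild_labels()
    values = np.zeros((len(table.sample_ids), len(labels)))
    for j, lab in enumerate(labels):
        members = [o for o in assignment.members(lab) if o in table.otu_ids]
        if not members:
            raise ValueError(f"guild {lab!r} has no members present in the table")
        idx = [table.otu_ids.index(o) for o in members]
        values[:, j] = table.values[:, idx].sum(axis=1)
    return AbundanceTable(list(table.sample_ids), labels, values, "relative")


@dataclass
class EdgeList:
    """Co-response network: retained edges plus per-node annotations."""

    edges: pd.DataFrame  # columns: source, target, rho, p, q
    nodes: pd.DataFrame  # index otu_id; columns: mean_shift, direction, guild

    def to_graph(self):
        import networkx as nx

        g = nx.Graph()
        for otu, row in self.nodes.iterrows():
            g.add_node(otu, **row.to_dict())
        for _, row in self.edges.iterrows():
            g.add_edge(row["source"], row["target"], rho=row["rho"], q=row["q"])
        return g

    def write_graphml(self, path) -> None:
        import networkx as nx

        nx.write_graphml(self.to_graph(), path)

    def write_edges_tsv(self, path) -> None:
        self.edges.to_csv(path, sep="\t", index=False)


def coresponse_network(
    shifts: ShiftMatrix,
    otus: list[str] | None = None,
    n_perm: int = 1000,
    rho_threshold: float = 0.5,
    q_threshold: float = 0.05,
    seed: int = 0,
    assignment: GuildAssignment | None = None,
) -> EdgeList:
    """Permutation-tested Spearman co-response network over OTU shifts.

    For each OTU pair, the permutation p value is
    ``(1 + #{perm |rho*| >= |rho|}) / (n_perm + 1)`` where one member's
    subject order is permuted; BH-FDR is applied across all pairs, and an
    edge is retained when ``|rho| >= rho_threshold`` and ``q < q_threshold``.
    """
    sub = shifts if otus is None else shifts.select_otus(list(otus))
    n, k = sub.values.shape
    if n < 5:
        raise ValueError("need at least five subjects")
    constant = [o for j, o in enumerate(sub.otu_ids) if np.ptp(sub.values[:, j]) == 0]
    if constant:
        warnings.warn(
            f"skipping OTUs with constant shifts: {constant}", stacklevel=2
        )
        keep = [o for o in sub.otu_ids if o not in constant]
        sub = sub.select_otus(keep)
        n, k = sub.values.shape
    ranks = sps.rankdata(sub.values, axis=0)
    z = ranks - ranks.mean(axis=0)
    norms = np.sqrt((z**2).sum(axis=0))
    z = z / norms
    rho = z.T @ z  # Spearman rho via Pearson on average ranks
    rng = np.random.default_rng(seed)
    perms = np.vstack([rng.permutation(n) for _ in range(n_perm)])
    abs_rho = np.abs(rho)
    exceed = np.zeros((k, k), dtype=np.int64)
    for p in range(n_perm):
        rho_perm = z[perms[p]].T @ z  # permute first member of every pair
        exceed += np.abs(rho_perm) >= abs_rho - 1e-12
    iu = np.triu_indices(k, 1)
    p_vals = (1 + exceed[iu]) / (n_perm + 1)
    q_vals = bh_fdr(p_vals)
    rows = []
    for (i, j), rho_ij, p_ij, q_ij in zip(zip(*iu), rho[iu], p_vals, q_vals):
        if abs(rho_ij) >= rho_threshold and q_ij < q_threshold:
            rows.append(
                {
                    "source": sub.otu_ids[i],
                    "target": sub.otu_ids[j],
                    "rho": float(rho_ij),
                    "p": float(p_ij),
                    "q": float(q_ij),
                }
            )
    edges = pd.DataFrame(rows, columns=["source", "target", "rho", "p", "q"])
    mean_shift = sub.values.mean(axis=0)
    nodes = pd.DataFrame(
        {
            "otu_id": sub.otu_ids,
            "mean_shift": mean_shift,
            "direction": np.sign(mean_shift).astype(int),
            "guild": [
                assignment.labels.get(o, "") if assignment else ""
                for o in sub.otu_ids
            ],
        }
    ).set_index("otu_id")
    return EdgeList(edges=edges, nodes=nodes)
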