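"""Phylogenetic machinery: Newick I/O, backbone grafting, covariance and eigenvectors.

Trees are represented as :class:`dendropy.Tree` objects with species tip labels
of the form ``Genus_species``.  Branch lengths are in arbitrary time units
(relative units are fine; covariances are standardized downstream).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd


class NewickFormatError(ValueError):
    """Raised when a Newick string/file cannot be parsed."""


def read_newick(path) -> dendropy.Tree:
    """Read a rooted tree from a Newick file.

    Underscores in labels are preserved verbatim (no conversion to spaces),
    and unlabeled internal nodes are accepted.
    """
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several error classes
        raise NewickFormatError(f"failed to parse Newick file {path!s}: {exc}") from exc
    tree.is_rooted = True
    return tree


def read_newick_string(s: str) -> dendropy.Tree:
    """Parse a Newick string (same dialect tolerance as :func:`read_newick`)."""
    try:
        tree = dendropy.Tree.get(data=s, schema="newick", preserve_underscores=True)
    except Exception as exc:
        raise NewickFormatError(f"failed to parse Newick string: {exc}") from exc
    tree.is_rooted = True
    return tree


def write_newick(tree: dendropy.Tree, path) -> None:
    """Write a tree to Newick, preserving branch lengths to full precision."""
    tree.write(
        path=str(path),
        schema="newick",
        unquoted_underscores=True,
        suppress_rooting=True,
        real_value_format_specifier=".17g",
    )


def tip_labels(tree: dendropy.Tree) -> list[str]:
    """Tip labels in stable leaf-iteration order."""
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def _root_distances(tree: dendropy.Tree) -> dict:
    """Distance from the root for every node (missing edge lengths count 0)."""
    dist = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            dist[node] = 0.0
        else:
            bl = node.edge.length if node.edge.length is not None else 0.0
            dist[node] = dist[node.parent_node] + bl
    return dist


def phylo_covariance(
    tree: dendropy.Tree, standardize: bool = True
) -> tuple[np.ndarray, list[str]]:
    """Brownian-motion variance-covariance matrix of the tips.

    ``C[i, j]`` is the shared root-to-MRCA path length of tips *i* and *j*.
    With ``standardize=True`` the matrix is rescaled to a correlation matrix
    (unit diagonal), which is what enters the mixed model as the species
    covariance.  A zero-depth tree yields the identity.  The result is forced
    positive semi-definite by flooring negative eigenvalues at zero (with a
    warning), which can only trigger through floating-point noise.
    """
    labels = tip_labels(tree)
    S = len(labels)
    index = {lab: i for i, lab in enumerate(labels)}
    C = np.zeros((S, S))
    # accumulate each edge length onto all pairs of tips below the edge
    tips_below: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            tips_below[node] = [index[node.taxon.label]]
        else:
            tips_below[node] = [
                i for ch in node.child_nodes() for i in tips_below[ch]
            ]
        if node.parent_node is not None and node.edge.length:
            idx = np.asarray(tips_below[node])
            C[np.ix_(idx, idx)] += node.edge.length
    d = np.diag(C).copy()
    if np.all(d <= 0):
        return np.eye(S), labels
    if standardize:
        dd = np.where(d > 0, d, 1.0)
        C = C / np.sqrt(np.outer(dd, dd))
        np.fill_diagonal(C, 1.0)
    eigvals = np.linalg.eigvalsh(C)
    if eigvals[0] < -1e-10 * max(1.0, eigvals[-1]):
        warnings.warn(
            "phylogenetic covariance not PSD; flooring negative eigenvalues at 0"
        )
        w, U = np.linalg.eigh(C)
        C = (U * np.clip(w, 0.0, None)) @ U.T
        C = (C + C.T) / 2
    return C, labels


def patristic_distances(tree: dendropy.Tree) -> tuple[np.ndarray, list[str]]:
    """Pairwise tip-to-tip path lengths (patristic distances)."""
    C, labels = phylo_covariance(tree, standardize=False)
    d = np.diag(C)
    D = d[:, None] + d[None, :] - 2 * C
    np.fill_diagonal(D, 0.0)
    return D, labels


def phylo_eigenvectors(
    tree: dendropy.Tree, k: int = 10
) -> tuple[np.ndarray, list[str]]:
    """Principal-coordinate axes of the patristic distance matrix.

    Classical PCoA: double-center ``-0.5 * D**2``, eigendecompose, keep axes
    with non-negative eigenvalues ordered by descending eigenvalue, scale by
    ``sqrt(eigenvalue)``.  Returns at most ``k`` columns (fewer if the matrix
    has fewer non-negative axes).
    """
    D, labels = patristic_distances(tree)
    S = D.shape[0]
    if k >= S:
        raise ValueError(f"k={k} must be smaller than the number of tips ({S})")
    H = np.eye(S) - np.ones((S, S)) / S
    B = -0.5 * H @ (D**2) @ H
    B = (B + B.T) / 2
    w, U = np.linalg.eigh(B)
    order = np.argsort(w)[::-1]
    w, U = w[order], U[:, order]
    keep = w > 1e-10 * max(1.0, abs(w).max())
    w, U = w[keep], U[:, keep]
    coords = U * np.sqrt(w)
    return coords[:, :k], labels


# ---------------------------------------------------------------------------
# grafting missing species onto a backbone
# ---------------------------------------------------------------------------


@dataclass
class GraftResult:
    tree: dendropy.Tree
    unresolved: list[str] = field(default_factory=list)
    #: species -> one of {"already_present", "genus_polytomy",
    #: "single_tip_genus", "family_midpoint", "family_two_thirds"}
    placements: dict = field(default_factory=dict)

    def unresolved_report(self) -> pd.DataFrame:
        return pd.DataFrame({"species": self.unresolved})


def _genus(name: str) -> str:
    return name.split("_", 1)[0]


def _genus_family_map(taxonomy) -> dict:
    """Accept a DataFrame (species, genus, family) or a genus->family mapping."""
    if isinstance(taxonomy, pd.DataFrame):
        return dict(zip(taxonomy["genus"], taxonomy["family"]))
    return dict(taxonomy)


def _mrca_node(nodes):
    """MRCA by root-path intersection (robust to in-progress tree surgery)."""
    paths = []
    for nd in nodes:
        p, cur = [], nd
        while cur is not None:
            p.append(cur)
            cur = cur.parent_node
        paths.append(p)
    common = set(paths[0])
    for p in paths[1:]:
        common &= set(p)
    for nd in paths[0]:
        if nd in common:
            return nd
    return None


def graft_species(
    backbone: dendropy.Tree, species_list: list[str], taxonomy
) -> GraftResult:
    """Attach species missing from the backbone using taxonomic rules.

    Rules, applied per species (genus parsed from the ``Genus_species`` name):

    1. Genus present in the backbone with >= 2 tips: the species joins as an
       extra child (polytomy) of the genus crown node, contemporaneous with
       the existing genus tips.
    2. Genus present with a single tip: a new node is inserted halfway along
       that tip's terminal branch and both species descend from it.
    3. Genus absent but the family is represented: a new genus node is bound
       at the midpoint between the family root node (the stem node where the
       family branch attaches) and the family basal node (the family crown);
       if the family branch is longer than two-thirds of the family
       root-to-tip length, the node is bound instead at the upper third of
       the family branch (age = family-root age minus one-third of the
       family branch length).
    4. Genus and family both absent: the species is listed as unresolved,
       never silently dropped.

    Grafted tips are placed at age zero (ultrametric grafting), so an
    ultrametric backbone stays ultrametric.
    """
    fam_of_genus = _genus_family_map(taxonomy)
    tree = backbone.clone(depth=1)
    tree.is_rooted = True
    result = GraftResult(tree=tree)

    def ages():
        dist = _root_distances(tree)
        depth = max(dist[leaf] for leaf in tree.leaf_node_iter())
        return {node: depth - d for node, d in dist.items()}

    def attach_tip(parent_node, label, length):
        taxon = tree.taxon_namespace.new_taxon(label=label)
        child = parent_node.new_child(taxon=taxon, edge_length=max(length, 0.0))
        return child

    def insert_node_on_edge(child_node, new_age, age_map):
        """Insert a degree-2 node on the branch above ``child_node`` at ``new_age``."""
        parent = child_node.parent_node
        upper = age_map[parent] - new_age
        lower = new_age - age_map[child_node]
        parent.remove_child(child_node)
        mid = parent.new_child(edge_length=max(upper, 0.0))
        mid.add_child(child_node)
        child_node.edge.length = max(lower, 0.0)
        return mid

    existing = set(tip_labels(tree))
    new_genus_nodes: dict = {}  # genus -> (node, attach_age) for absent genera

    for sp in species_list:
        if sp in existing:
            result.placements[sp] = "already_present"
            continue
        genus = _genus(sp)
        age_map = ages()
        genus_tips = [
            leaf for leaf in tree.leaf_node_iter()
            if _genus(leaf.taxon.label) == genus
        ]
        if genus in new_genus_nodes:
            node, attach_age = new_genus_nodes[genus]
            attach_tip(node, sp, attach_age)
            result.placements[sp] = result.placements.get(
                f"__genus__{genus}", "family_midpoint"
            )
            existing.add(sp)
            continue
        if len(genus_tips) >= 2:
            mrca = _mrca_node(genus_tips)
            attach_tip(mrca, sp, age_map[mrca])
            result.placements[sp] = "genus_polytomy"
            existing.add(sp)
            continue
        if len(genus_tips) == 1:
            tip = genus_tips[0]
            split_age = (age_map[tip.parent_node] + age_map[tip]) / 2.0
            mid = insert_node_on_edge(tip, split_age, age_map)
            attach_tip(mid, sp, split_age)
            result.placements[sp] = "single_tip_genus"
            existing.add(sp)
            continue
        # genus absent: try the family
        family = fam_of_genus.get(genus)
        fam_tips = [
            leaf for leaf in tree.leaf_node_iter()
            if fam_of_genus.get(_genus(leaf.taxon.label)) == family
        ]
        if family is None or not fam_tips:
            result.unresolved.append(sp)
            continue
        if len(fam_tips) >= 2:
            crown = _mrca_node(fam_tips)
        else:
            crown = fam_tips[0]
        stem = crown.parent_node
        if stem is None:
            # family spans the whole tree: bind at the root as a polytomy
            attach_age = age_map[crown]
            node = crown
        else:
            age_stem = age_map[stem]
            age_crown = age_map[crown]
            fam_branch = age_stem - age_crown
            if fam_branch > (2.0 / 3.0) * age_stem:
                attach_age = age_stem - fam_branch / 3.0
                case = "family_two_thirds"
            else:
                attach_age = (age_stem + age_crown) / 2.0
                case = "family_midpoint"
            node = insert_node_on_edge(crown, attach_age, age_map)
            result.placements[f"__genus__{genus}"] = case
        attach_tip(node, sp, attach_age)
        new_genus_nodes[genus] = (node, attach_age)
        result.placements[sp] = result.placements.get(
            f"__genus__{genus}", "family_midpoint"
        )
        existing.add(sp)

    # drop bookkeeping keys
    result.placements = {
        k: v for k, v in result.placements.items() if not k.startswith("__genus__")
    }
    return result
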