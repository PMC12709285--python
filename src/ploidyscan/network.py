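"""Protein-interaction degree statistics and the mean-degree permutation
test for candidate gene sets.

Connectivity (degree: number of distinct interaction partners) serves as a
proxy for pleiotropy.  Edges come from a STRING-format TSV (protein1,
protein2, combined_score); no score threshold is applied by default.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def load_edges(path_or_frame, score_threshold: float = 0) -> pd.Series:
    """Build the degree table from an edge list.

    Undirected edges are deduplicated (A-B and B-A count once), self-loops
    dropped (count logged), and edges below ``score_threshold`` removed.
    Returns protein_id -> degree."""
    if isinstance(path_or_frame, pd.DataFrame):
        edges = path_or_frame.copy()
    else:
        edges = pd.read_csv(path_or_frame, sep="\t")
    required = {"protein1", "protein2", "combined_score"}
    if not required <= set(edges.columns):
        raise ValueError(f"edge list needs columns {sorted(required)}")
    n_self = int((edges["protein1"] == edges["protein2"]).sum())
    if n_self:
        logger.info("dropped %d self-loops", n_self)
    edges = edges[edges["protein1"] != edges["protein2"]]
    edges = edges[edges["combined_score"] >= score_threshold]
    g = nx.Graph()
    g.add_edges_from(zip(edges["protein1"], edges["protein2"]))
    if g.number_of_edges() == 0:
        logger.warning("no edges above score threshold %s", score_threshold)
    degrees = pd.Series(dict(g.degree), dtype=int, name="degree")
    return degrees.sort_index()


def map_ids(candidate_genes, mapping: pd.DataFrame, degrees: pd.Series):
    """Degrees of mappable candidate genes plus the unmapped list.

    ``mapping`` has columns gene_id, protein_id (duplicate gene rows keep
    the first, with a warning).  Genes without a mapping row or without a
    node in the degree table are reported as unmapped and excluded."""
    if mapping["gene_id"].duplicated().any():
        logger.warning("duplicate mapping rows: keeping first per gene")
        mapping = mapping.drop_duplicates("gene_id", keep="first")
    lut = mapping.set_index("gene_id")["protein_id"]
    mapped = {}
    unmapped = []
    for g in sorted(candidate_genes):
        prot = lut.get(g)
        if prot is None or prot not in degrees.index:
            unmapped.append(g)
        else:
            mapped[g] = int(degrees[prot])
    return pd.Series(mapped, dtype=int, name="degree"), unmapped


def degree_permutation_test(
    candidate_degrees, all_degrees, n_perm: int = 10_000, seed: int = 0
) -> dict:
    """One-sided permutation test of mean candidate degree vs same-size
    random draws (without replacement) from the full degree table.

    p = (1 + #{null >= observed}) / (n_perm + 1)."""
    cand = np.asarray(candidate_degrees, dtype=float)
    pool = np.asarray(all_degrees, dtype=float)
    if len(cand) == 0:
        raise ValueError("empty candidate degree vector")
    observed = float(cand.mean())
    rng = np.random.default_rng(seed)
    k = len(cand)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = pool[rng.choice(len(pool), size=k, replace=False)].mean()
    # tolerance so numerically-equal null means count as >= observed
    tol = 1e-9 * max(1.0, abs(observed))
    p = (1.0 + float((null >= observed - tol).sum())) / (n_perm + 1.0)
    return {"observed_mean": observed, "p": p, "n_candidates": k}
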