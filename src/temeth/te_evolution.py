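"""Subfamily clustering, Dollo-parsimony dynamics and Ka/Ks selection tests.

The workflow mirrors how young retroelement lineages are characterised:
pairwise amino-acid identities become a weighted network whose connected
components (at 0.8 within-genome / 0.6 cross-species identity) are
subfamilies; subfamily presence across species is reconstructed under Dollo
parsimony (one gain, unlimited losses); and purifying selection on domains
is screened with Nei-Gojobori (1986) Ka/Ks on back-translated codon
alignments, with Jukes-Cantor correction and an explicit saturation flag.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "CodonPair",
    "pairwise_identity",
    "sequence_identity",
    "dedup_identical",
    "cluster_components",
    "build_presence_matrix",
    "dollo_parsimony",
    "backtranslate_alignment",
    "filter_gap_rich",
    "kaks_ng86",
    "best_interspecies_hit",
]


# --------------------------------------------------------------------------
# identity network


def sequence_identity(a: str, b: str) -> float:
    """Global identity of two sequences: 1 - edit_distance / max(len).

    Uses the unit-cost Needleman-Wunsch distance (edlib), which makes the
    value independent of which co-optimal alignment is traced.
    """
    import edlib

    if not a or not b:
        return 0.0
    d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return 1.0 - d / max(len(a), len(b))


def dedup_identical(seqs: dict) -> dict:
    """Drop sequences identical at the amino-acid level (first id kept)."""
    seen: dict[str, str] = {}
    out = {}
    for sid, s in seqs.items():
        if s not in seen:
            seen[s] = sid
            out[sid] = s
    return out


def pairwise_identity(seqs: dict | None = None,
                      hit_table: pd.DataFrame | None = None,
                      species: dict | None = None) -> nx.Graph:
    """Identity network: sequences as nodes, identities as edge weights.

    Either ``seqs`` (id -> sequence; all-versus-all global identities) or a
    tabular hit table with columns qseqid, sseqid, pident (percent or
    fraction) and optionally bitscore. Self-hits are excluded and asymmetric
    hits collapsed to their maximum. ``species`` labels nodes for the
    presence-matrix stage.
    """
    g = nx.Graph()
    if (seqs is None) == (hit_table is None):
        raise ValueError("provide exactly one of seqs or hit_table")
    if seqs is not None:
        ids = list(seqs)
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sequence ids")
        g.add_nodes_from(ids)
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                g.add_edge(a, b, weight=sequence_identity(seqs[a], seqs[b]))
    else:
        for r in hit_table.itertuples():
            q, s = r.qseqid, r.sseqid
            if q == s:
                continue
            ident = float(r.pident)
            if ident > 1.0:
                ident /= 100.0
            g.add_node(q)
            g.add_node(s)
            if g.has_edge(q, s):
                g[q][s]["weight"] = max(g[q][s]["weight"], ident)
            else:
                g.add_edge(q, s, weight=ident)
    if species:
        missing = [n for n in g.nodes if n not in species]
        if missing:
            raise ValueError(f"sequences without species label: {missing[:5]}")
        nx.set_node_attributes(g, species, "species")
    return g


def cluster_components(graph: nx.Graph, threshold: float) -> list:
    """Connected components after dropping edges below ``threshold``.

    Singletons are kept; components are returned as sorted id lists, ordered
    by (size desc, first id) for reproducibility.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    kept = nx.Graph()
    kept.add_nodes_from(graph.nodes(data=True))
    kept.add_edges_from((u, v) for u, v, w in graph.edges(data="weight")
                        if w >= threshold)
    comps = [sorted(c) for c in nx.connected_components(kept)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    return comps


def build_presence_matrix(components: list, species_map: dict,
                          all_species: list | None = None):
    """Binary subfamily x species matrix plus per-species copy counts."""
    if all_species is None:
        all_species = sorted(set(species_map.values()))
    presence = []
    counts = []
    index = []
    for i, comp in enumerate(components):
        tallies = {s: 0 for s in all_species}
        for sid in comp:
            if sid not in species_map:
                raise ValueError(f"sequence {sid!r} has no species label")
            tallies[species_map[sid]] += 1
        index.append(f"sf{i + 1}")
        counts.append([tallies[s] for s in all_species])
        presence.append([1 if tallies[s] else 0 for s in all_species])
    pres = pd.DataFrame(presence, index=index, columns=all_species)
    cnt = pd.DataFrame(counts, index=index, columns=all_species)
    return pres, cnt


# --------------------------------------------------------------------------
# Dollo parsimony


def _load_tree(tree):
    import dendropy

    if isinstance(tree, dendropy.Tree):
        t = tree
    else:
        data = str(tree)
        if "(" not in data:  # a path
            t = dendropy.Tree.get(path=data, schema="newick",
                                  rooting="force-rooted")
        else:
            t = dendropy.Tree.get(data=data, schema="newick",
                                  rooting="force-rooted")
    if t.is_rooted is False and len(t.seed_node.child_nodes()) > 2:
        raise ValueError("Dollo parsimony needs a rooted tree")
    return t


def _node_name(n):
    return n.taxon.label if n.taxon else (n.label or "")


def dollo_parsimony(tree, matrix: pd.DataFrame):
    """Single-gain, minimal-loss reconstruction for each subfamily.

    The gain is placed at the MRCA of all present tips; losses are the
    maximal subtrees under the gain node containing no present tip (pruning
    one edge each explains every absence). Returns a per-subfamily frame
    (gain node, loss edges, n_losses) and per-branch gain/loss totals.
    """
    t = _load_tree(tree)
    nodes = list(t.preorder_node_iter())
    for i, n in enumerate(nodes):
        if n.taxon is None and not getattr(n, "label", None):
            n.label = f"n{i}"
    tip_names = {_node_name(l) for l in t.leaf_node_iter()}
    missing = set(matrix.columns) - tip_names
    if missing:
        raise ValueError(f"matrix species not in tree: {sorted(missing)}")

    taxon_by_name = {taxon.label: taxon for taxon in t.taxon_namespace}
    rows = []
    gain_totals: dict[str, int] = {}
    loss_totals: dict[str, int] = {}
    for subfam, states in matrix.iterrows():
        present = {sp for sp in matrix.columns if states[sp] == 1}
        if not present:
            rows.append((subfam, None, (), 0))
            continue
        if len(present) == 1:
            (only,) = present
            gain = t.find_node_with_taxon_label(only)
        else:
            gain = t.mrca(taxa=[taxon_by_name[s] for s in present])
        losses: list[str] = []

        def _walk(node):
            tips_below = {_node_name(l) for l in node.leaf_iter()}
            if not tips_below & present:
                losses.append(_node_name(node))
                return
            for child in node.child_nodes():
                _walk(child)

        for child in gain.child_nodes():
            _walk(child)
        gname = _node_name(gain)
        rows.append((subfam, gname, tuple(sorted(losses)), len(losses)))
        gain_totals[gname] = gain_totals.get(gname, 0) + 1
        for e in losses:
            loss_totals[e] = loss_totals.get(e, 0) + 1

    per_subfamily = pd.DataFrame(
        rows, columns=["subfamily", "gain_node", "loss_edges", "n_losses"])
    branch_names = sorted({_node_name(n) for n in nodes})
    totals = pd.DataFrame({
        "branch": branch_names,
        "gains": [gain_totals.get(b, 0) for b in branch_names],
        "losses": [loss_totals.get(b, 0) for b in branch_names]})
    return per_subfamily, totals


# --------------------------------------------------------------------------
# codon alignments


def _translate(cds: str) -> str:
    from Bio.Seq import Seq

    return str(Seq(cds).translate())


def backtranslate_alignment(protein_aln: dict, cds: dict) -> dict:
    """Thread source codons through a protein alignment.

    Each aligned residue becomes its source codon and each gap a triple gap.
    Every CDS must translate exactly to its ungapped protein (a terminal
    stop codon on the CDS is tolerated); a mismatch raises an error naming
    the offending codon.
    """
    out = {}
    for sid, prot in protein_aln.items():
        if sid not in cds:
            raise ValueError(f"no CDS for {sid!r}")
        nt = cds[sid].upper().replace("U", "T")
        if len(nt) % 3:
            raise ValueError(f"{sid}: CDS length {len(nt)} not a multiple of 3")
        aa = _translate(nt)
        if aa.endswith("*"):
            aa = aa[:-1]
            nt = nt[:-3]
        ungapped = prot.replace("-", "")
        if len(aa) != len(ungapped):
            raise ValueError(
                f"{sid}: CDS translates to {len(aa)} aa, alignment has "
                f"{len(ungapped)}")
        for i, (x, y) in enumerate(zip(aa, ungapped)):
            if x != y and x != "X" and y != "X":
                raise ValueError(
                    f"{sid}: translation mismatch at codon {i + 1}: "
                    f"CDS gives {x!r}, alignment has {y!r}")
        codons = iter(nt[i:i + 3] for i in range(0, len(nt), 3))
        out[sid] = "".join("---" if c == "-" else next(codons) for c in prot)
    return out


def filter_gap_rich(alignment: dict, min_occupancy: float = 0.5) -> dict:
    """Drop sequences occupying fewer than ``min_occupancy`` of the columns."""
    ncol = max((len(s) for s in alignment.values()), default=0)
    return {sid: s for sid, s in alignment.items()
            if ncol and (len(s) - s.count("-")) / ncol >= min_occupancy}


# --------------------------------------------------------------------------
# Nei-Gojobori Ka/Ks


@dataclass
class CodonPair:
    """NG86 decomposition of one aligned coding-sequence pair."""

    n_codons: int
    N: float
    S: float
    Nd: float
    Sd: float
    pn: float
    ps: float
    ka: float
    ks: float
    ratio: float
    saturated: bool


_STOPS = {"TAA", "TAG", "TGA"}
SATURATION_PS = 0.74  # Jukes-Cantor domain boundary 3/4, minus tolerance


@lru_cache(maxsize=None)
def _codon_aa(codon: str) -> str:
    from Bio.Seq import Seq

    return str(Seq(codon).translate())


@lru_cache(maxsize=None)
def _codon_sites(codon: str):
    """(synonymous, nonsynonymous) site counts of one codon.

    Each position contributes the fraction of its three possible changes
    that preserve the amino acid; changes creating a stop count as
    nonsynonymous.
    """
    aa = _codon_aa(codon)
    s = 0.0
    for pos in range(3):
        syn = 0
        for b in "ACGT":
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if alt not in _STOPS and _codon_aa(alt) == aa:
                syn += 1
        s += syn / 3.0
    return s, 3.0 - s


@lru_cache(maxsize=None)
def _codon_path_diffs(c1: str, c2: str):
    """(syn, nonsyn) differences between two codons, averaged with equal
    weight over all minimal mutational pathways; pathways through stop
    codons are excluded (all pathways counted if none avoids a stop)."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0

    def walk(include_stops: bool):
        results = []
        for order in itertools.permutations(diff):
            cur = c1
            sd = nd = 0
            ok = True
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
                if nxt in _STOPS and nxt != c2 and not include_stops:
                    ok = False
                    break
                if nxt in _STOPS or cur in _STOPS or \
                        _codon_aa(cur) != _codon_aa(nxt):
                    nd += 1
                else:
                    sd += 1
                cur = nxt
            if ok:
                results.append((sd, nd))
        return results

    paths = walk(False)
    if not paths:
        paths = walk(True)
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def _jc(p: float) -> float:
    return -0.75 * float(np.log(1.0 - 4.0 * p / 3.0))


def kaks_ng86(seq_a: str, seq_b: str) -> CodonPair:
    """Nei-Gojobori (1986) Ka/Ks with Jukes-Cantor correction.

    Site counts are averaged over the two sequences; multi-step codon
    differences average all minimal mutational pathways with equal weight.
    pS >= 0.74 marks synonymous saturation (Ks undefined); the ratio is
    undefined when Ks is zero or undefined.
    """
    a = seq_a.upper().replace("U", "T")
    b = seq_b.upper().replace("U", "T")
    if len(a) != len(b):
        raise ValueError("aligned sequences differ in length")
    if len(a) % 3:
        raise ValueError("alignment length not a multiple of 3")
    codons = []
    for i in range(0, len(a), 3):
        ca, cb = a[i:i + 3], b[i:i + 3]
        if "-" in ca or "-" in cb:
            continue
        if ca in _STOPS or cb in _STOPS:
            if i == len(a) - 3:  # shared reading-frame end
                continue
            raise ValueError(f"in-frame stop codon at alignment codon "
                             f"{i // 3 + 1}")
        if set(ca + cb) - set("ACGT"):
            continue
        codons.append((ca, cb))
    if not codons:
        raise ValueError("no ungapped codon pairs in alignment")

    N = S = Nd = Sd = 0.0
    for ca, cb in codons:
        sa, na = _codon_sites(ca)
        sb, nb = _codon_sites(cb)
        S += (sa + sb) / 2
        N += (na + nb) / 2
        sd, nd = _codon_path_diffs(ca, cb)
        Sd += sd
        Nd += nd

    pn = Nd / N if N else float("nan")
    ps = Sd / S if S else float("nan")
    saturated = bool(ps >= SATURATION_PS)
    ka = _jc(pn) if pn < 0.75 else float("nan")
    ks = _jc(ps) if not saturated else float("nan")
    if np.isnan(ks) or ks == 0:
        ratio = float("nan")
    else:
        ratio = ka / ks
    return CodonPair(n_codons=len(codons), N=N, S=S, Nd=Nd, Sd=Sd,
                     pn=pn, ps=ps, ka=ka, ks=ks, ratio=ratio,
                     saturated=saturated)


# --------------------------------------------------------------------------
# cross-species partners


def best_interspecies_hit(hit_table: pd.DataFrame, query_id: str,
                          query_species: str,
                          species_map: dict) -> str | None:
    """Highest-bitscore hit outside the query's species.

    Ties break by identity, then lexical subject id; None when the query has
    no cross-species hit.
    """
    sub = hit_table[hit_table["qseqid"] == query_id]
    rows = []
    for r in sub.itertuples():
        sp = species_map.get(r.sseqid)
        if sp is None or sp == query_species:
            continue
        ident = getattr(r, "pident", 0.0)
        rows.append((-float(r.bitscore), -float(ident), str(r.sseqid)))
    if not rows:
        return None
    rows.sort()
    return rows[0][2]
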