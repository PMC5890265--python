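"""Methylome statistics: global levels, site/read distributions, CG symmetry,
metaplots, TE 3' CH enrichment, DMRs, and expression correlation.

Levels are read-weighted throughout (sum of methylated calls over sum of
informative calls), not averages of per-site ratios; the two only coincide at
uniform coverage.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .calling import MethylomeTable

__all__ = [
    "FeatureSet",
    "MetaProfile",
    "DMR",
    "global_levels",
    "site_level_distribution",
    "read_level_distribution",
    "symmetric_cg_concordance",
    "metaplot",
    "te_3prime_ch_enrichment",
    "find_dmrs",
    "expression_methylation_correlation",
    "gene_body_levels",
]

CONTEXT_GROUPS = ("CG", "CHG", "CHH", "CH", "CA", "CT", "CC")


@dataclass
class FeatureSet:
    """Genomic features, internally 0-based half-open.

    Columns: contig, start, end, strand (+/-/.), kind (gene/TE/other), id,
    family, tpm (optional, NaN when absent).
    """

    table: pd.DataFrame

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "FeatureSet":
        df = df.copy()
        if "tpm" not in df.columns:
            df["tpm"] = np.nan
        if "family" not in df.columns:
            df["family"] = "."
        return cls(df.reset_index(drop=True))

    @classmethod
    def from_bed(cls, path: str, kind: str = "other") -> "FeatureSet":
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        df = df.iloc[:, :6]
        df.columns = ["contig", "start", "end", "id", "score", "strand"][: df.shape[1]]
        if "strand" not in df.columns:
            df["strand"] = "."
        df["kind"] = kind
        return cls.from_dataframe(df[["contig", "start", "end", "strand",
                                      "kind", "id"]])

    @classmethod
    def from_gff3(cls, path: str) -> "FeatureSet":
        rows = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                f = line.rstrip("\n").split("\t")
                attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
                kind = "gene" if f[2] == "gene" else \
                    ("TE" if f[2] in ("repeat_region", "transposable_element")
                     else "other")
                rows.append((f[0], int(f[3]) - 1, int(f[4]), f[6], kind,
                             attrs.get("ID", f"{f[0]}:{f[3]}"),
                             attrs.get("family", ".")))
        return cls.from_dataframe(pd.DataFrame(
            rows, columns=["contig", "start", "end", "strand", "kind", "id",
                           "family"]))

    def with_expression(self, expr: pd.DataFrame) -> "FeatureSet":
        lut = dict(zip(expr.iloc[:, 0], expr.iloc[:, 1]))
        df = self.table.copy()
        df["tpm"] = df["id"].map(lut)
        return FeatureSet(df)

    def subset(self, kind: str) -> pd.DataFrame:
        return self.table[self.table["kind"] == kind]


@dataclass
class MetaProfile:
    """Mean +/- SD methylation over relative positions around features."""

    contexts: tuple
    mean: dict  # context -> (flank+body+flank,) array
    sd: dict
    n_features: int
    body_bins: int
    flank_bins: int
    flank_bp: int

    def to_frame(self) -> pd.DataFrame:
        n = self.flank_bins * 2 + self.body_bins
        rows = {"bin": np.arange(n)}
        for c in self.contexts:
            rows[f"{c}_mean"] = self.mean[c]
            rows[f"{c}_sd"] = self.sd[c]
        return pd.DataFrame(rows)


@dataclass
class DMR:
    contig: str
    start: int  # 0-based half-open
    end: int
    n_cg: int
    delta: float
    p_value: float
    direction: str  # hyper (A>B) | hypo


def _group_mask(df: pd.DataFrame, group: str) -> pd.Series:
    if group in ("CG", "CHG", "CHH"):
        return df["context"] == group
    if group == "CH":
        return df["context"].isin(("CHG", "CHH"))
    if group in ("CA", "CT", "CC"):
        return df["dinuc"] == group[1]
    raise ValueError(f"unknown context group {group!r}")


def global_levels(table: MethylomeTable, groups=CONTEXT_GROUPS,
                  by_contig: bool = False):
    """Weighted methylation level per context group (sum mc / sum total).

    Returns a Series (or DataFrame with a contig level when ``by_contig``);
    groups with zero informative coverage are NaN.
    """
    df = table.table
    if df.empty:
        raise ValueError("empty methylome table")

    def _levels(sub: pd.DataFrame) -> pd.Series:
        out = {}
        for g in groups:
            m = _group_mask(sub, g)
            tot = int(sub.loc[m, "total"].sum())
            out[g] = float(sub.loc[m, "mc"].sum() / tot) if tot else np.nan
        return pd.Series(out)

    if by_contig:
        return df.groupby("contig", sort=True).apply(_levels,
                                                     include_groups=False)
    return _levels(df)


def site_level_distribution(table: MethylomeTable, context: str = "CG",
                            min_cov: int = 10, bins: int = 20):
    """Distribution of per-site levels at well-covered sites.

    Returns dict with the histogram (density over [0,1]), the fraction of
    sites with exactly zero methylated calls ("completely unmethylated") and
    the fraction with level > 0.2.
    """
    if min_cov < 1:
        raise ValueError("min_cov must be >= 1")
    df = table.table
    sub = df[_group_mask(df, context) & (df["total"] >= min_cov)]
    levels = (sub["mc"] / sub["total"]).to_numpy()
    hist, edges = np.histogram(levels, bins=bins, range=(0.0, 1.0))
    n = levels.size
    return {
        "levels": levels,
        "hist": hist,
        "bin_edges": edges,
        "n_sites": n,
        "zero_fraction": float((sub["mc"] == 0).sum() / n) if n else np.nan,
        "gt02_fraction": float((levels > 0.2).mean()) if n else np.nan,
    }


def read_level_distribution(alignments, genome, min_cg_per_read: int = 5,
                            min_mapq: int = 10) -> np.ndarray:
    """Per-read (epiallele) methylation levels over reference-CG positions.

    For every read covering at least ``min_cg_per_read`` CG cytosines on its
    informative strand, level = methylated calls / informative (C-or-T
    equivalent) calls at those positions.
    """
    import pysam

    from .calling import _load_genome
    from .simulate import _context_arrays

    genome = _load_genome(genome)
    own = isinstance(alignments, str)
    af = pysam.AlignmentFile(alignments, check_sq=False) if own else alignments

    cg_mask = {}
    for contig, seq in genome.items():
        is_c, is_g, ctx_p, ctx_m = _context_arrays(seq)
        cg_mask[contig] = (is_c & (ctx_p == 0), is_g & (ctx_m == 0))

    levels = []
    for read in af:
        if (read.is_unmapped or read.is_secondary or read.is_supplementary
                or read.is_duplicate or read.mapping_quality < min_mapq):
            continue
        contig = read.reference_name
        if contig not in cg_mask:
            continue
        plus_cg, minus_cg = cg_mask[contig]
        seq = read.query_sequence
        meth_b, unmeth_b = ("G", "A") if read.is_reverse else ("C", "T")
        site_mask = minus_cg if read.is_reverse else plus_cg
        mc = tot = 0
        for qpos, rpos in read.get_aligned_pairs(matches_only=True):
            if site_mask[rpos]:
                b = seq[qpos]
                if b == meth_b:
                    mc += 1
                    tot += 1
                elif b == unmeth_b:
                    tot += 1
        if tot >= min_cg_per_read:
            levels.append(mc / tot)
    if own:
        af.close()
    return np.asarray(levels)


def symmetric_cg_concordance(table: MethylomeTable, min_cov: int = 10):
    """Correlation of methylation between the two strands of CG palindromes.

    Pairs a plus-strand CG at position i with the minus-strand record at
    i+1; both must reach ``min_cov``. Returns dict with paired levels,
    Pearson and Spearman r, and n_pairs (correlations NaN below 3 pairs).
    """
    df = table.table
    cg = df[(df["context"] == "CG") & (df["total"] >= min_cov)]
    plus = cg[cg["strand"] == "+"]
    minus = cg[cg["strand"] == "-"]
    merged = plus.assign(pair_pos=plus["pos"] + 1).merge(
        minus, left_on=["contig", "pair_pos"], right_on=["contig", "pos"],
        suffixes=("_p", "_m"))
    a = (merged["mc_p"] / merged["total_p"]).to_numpy()
    b = (merged["mc_m"] / merged["total_m"]).to_numpy()
    n = a.size
    if n >= 3 and np.std(a) > 0 and np.std(b) > 0:
        pearson = float(stats.pearsonr(a, b).statistic)
        spearman = float(stats.spearmanr(a, b).statistic)
    else:
        pearson = spearman = np.nan
    return {"plus": a, "minus": b, "n_pairs": n,
            "pearson": pearson, "spearman": spearman}


def metaplot(table: MethylomeTable, features, body_bins: int = 20,
             flank_bp: int = 2000, flank_bins: int = 20,
             contexts=("CG", "CH")) -> MetaProfile:
    """Scaled metaprofile (flank - body - flank) around oriented features.

    Each feature body is scaled to ``body_bins``; flanks use fixed-width
    bins. Minus-strand features are flipped so bin 0 is always upstream of
    the TSS. Per-feature, per-bin levels are weighted (sum mc / sum total);
    the profile reports the mean and SD across features, ignoring bins
    without covered cytosines.
    """
    feats = features.table if isinstance(features, FeatureSet) else features
    if len(feats) == 0:
        raise ValueError("empty feature set")
    df = table.table
    nbins = 2 * flank_bins + body_bins
    flank_w = flank_bp / flank_bins if flank_bins else 1.0

    sums = {c: [] for c in contexts}
    for c in contexts:
        sub = df[_group_mask(df, c)]
        by_contig = {k: (g["pos"].to_numpy() - 1, g["mc"].to_numpy(),
                         g["total"].to_numpy())
                     for k, g in sub.groupby("contig", sort=False)}
        for _, f in feats.iterrows():
            if f.contig not in by_contig:
                sums[c].append(np.full(nbins, np.nan))
                continue
            pos0, mc, tot = by_contig[f.contig]
            lo, hi = f.start - flank_bp, f.end + flank_bp
            sel = (pos0 >= lo) & (pos0 < hi)
            p, m, t = pos0[sel], mc[sel], tot[sel]
            length = f.end - f.start
            binidx = np.empty(p.size, dtype=np.int64)
            up = p < f.start
            down = p >= f.end
            body = ~(up | down)
            binidx[up] = ((p[up] - lo) / flank_w).astype(np.int64)
            binidx[body] = flank_bins + np.minimum(
                ((p[body] - f.start) / length * body_bins).astype(np.int64),
                body_bins - 1)
            binidx[down] = flank_bins + body_bins + np.minimum(
                ((p[down] - f.end) / flank_w).astype(np.int64), flank_bins - 1)
            mc_b = np.bincount(binidx, weights=m, minlength=nbins)
            tot_b = np.bincount(binidx, weights=t, minlength=nbins)
            with np.errstate(invalid="ignore", divide="ignore"):
                lv = np.where(tot_b > 0, mc_b / np.maximum(tot_b, 1), np.nan)
            if f.strand == "-":
                lv = lv[::-1]
            sums[c].append(lv)

    mean = {}
    sd = {}
    for c in contexts:
        mat = np.vstack(sums[c])
        with np.errstate(invalid="ignore"):
            mean[c] = np.nanmean(mat, axis=0)
            sd[c] = np.nanstd(mat, axis=0)
    return MetaProfile(contexts=tuple(contexts), mean=mean, sd=sd,
                       n_features=len(feats), body_bins=body_bins,
                       flank_bins=flank_bins, flank_bp=flank_bp)


def te_3prime_ch_enrichment(table: MethylomeTable, te_features,
                            tpm_threshold: float = 0.5,
                            min_mean_cov: float = 2.0,
                            tail_fraction: float = 0.25,
                            fold: float = 2.0) -> pd.DataFrame:
    """Classify transcribed, covered TEs by 3'-tail CH enrichment.

    TEs with TPM > ``tpm_threshold`` and mean per-cytosine coverage >
    ``min_mean_cov`` are 'enriched' when the weighted CH level over the
    3'-most ``tail_fraction`` of the body is at least ``fold`` times the
    level over the remainder; others are 'not_enriched'. TEs failing the
    filters are 'insufficient'.
    """
    feats = te_features.table if isinstance(te_features, FeatureSet) else te_features
    df = table.table
    ch = df[_group_mask(df, "CH")]
    rows = []
    for _, f in feats.iterrows():
        sub = ch[(ch["contig"] == f.contig) & (ch["pos"] - 1 >= f.start)
                 & (ch["pos"] - 1 < f.end)]
        mean_cov = float(sub["total"].mean()) if len(sub) else 0.0
        tpm = f.tpm if "tpm" in f.index else np.nan
        length = f.end - f.start
        tail = int(round(length * tail_fraction))
        if f.strand == "-":
            in_tail = sub["pos"] - 1 < f.start + tail
        else:
            in_tail = sub["pos"] - 1 >= f.end - tail
        t_tot = int(sub.loc[in_tail, "total"].sum())
        r_tot = int(sub.loc[~in_tail, "total"].sum())
        if (pd.isna(tpm) or tpm <= tpm_threshold or mean_cov <= min_mean_cov
                or t_tot == 0 or r_tot == 0):
            cls = "insufficient"
            tail_lv = rest_lv = np.nan
        else:
            tail_lv = sub.loc[in_tail, "mc"].sum() / t_tot
            rest_lv = sub.loc[~in_tail, "mc"].sum() / r_tot
            cls = "enriched" if tail_lv >= fold * max(rest_lv, 1e-12) \
                else "not_enriched"
        rows.append((f.id, tpm, mean_cov, tail_lv, rest_lv, cls))
    return pd.DataFrame(rows, columns=["id", "tpm", "mean_cov", "tail_level",
                                       "rest_level", "classification"])


@lru_cache(maxsize=200_000)
def _fisher_p(a: int, b: int, c: int, d: int) -> float:
    return float(stats.fisher_exact([[a, b], [c, d]])[1])


def _merged_cg_sites(df: pd.DataFrame) -> pd.DataFrame:
    """Collapse the two strands of each CG dinucleotide onto the C position."""
    cg = df[df["context"] == "CG"][["contig", "pos", "strand", "mc", "total"]]
    pos = np.where(cg["strand"] == "-", cg["pos"] - 1, cg["pos"])
    out = cg.assign(cg_pos=pos).groupby(["contig", "cg_pos"], as_index=False)[
        ["mc", "total"]].sum()
    return out


def find_dmrs(table_a: MethylomeTable, table_b: MethylomeTable,
              min_delta: float = 0.2, min_cg: int = 5,
              p_threshold: float = 0.01, min_cov: float = 4.0,
              max_gap: int = 300) -> list:
    """Differentially methylated regions between two libraries.

    Per CG dinucleotide (strands pooled) a Fisher exact test compares
    methylated/unmethylated counts; candidate sites (p < ``p_threshold``,
    consistent direction, gaps <= ``max_gap``) are merged, and a region is
    kept when it spans >= ``min_cg`` CGs, the pooled level difference
    reaches ``min_delta`` and mean site coverage in both samples reaches
    ``min_cov``. The region p combines per-site p-values by Stouffer's
    method with direction.
    """
    a = _merged_cg_sites(table_a.table)
    b = _merged_cg_sites(table_b.table)
    m = a.merge(b, on=["contig", "cg_pos"], suffixes=("_a", "_b"))
    m = m[(m["total_a"] > 0) & (m["total_b"] > 0)]
    if m.empty:
        return []
    m = m.sort_values(["contig", "cg_pos"]).reset_index(drop=True)

    pvals = np.array([
        _fisher_p(int(r.mc_a), int(r.total_a - r.mc_a),
                  int(r.mc_b), int(r.total_b - r.mc_b))
        for r in m.itertuples()])
    delta = (m["mc_a"] / m["total_a"] - m["mc_b"] / m["total_b"]).to_numpy()
    cand = (pvals < p_threshold) & (delta != 0)

    dmrs: list[DMR] = []
    idx = np.nonzero(cand)[0]
    if idx.size == 0:
        return dmrs
    contigs = m["contig"].to_numpy()
    pos = m["cg_pos"].to_numpy()
    sign = np.sign(delta)

    runs: list[list[int]] = [[idx[0]]]
    for i in idx[1:]:
        j = runs[-1][-1]
        if (contigs[i] == contigs[j] and pos[i] - pos[j] <= max_gap
                and sign[i] == sign[j]):
            runs[-1].append(i)
        else:
            runs.append([i])

    for run in runs:
        sel = m.iloc[run]
        n_cg = len(run)
        if n_cg < min_cg:
            continue
        lv_a = sel["mc_a"].sum() / sel["total_a"].sum()
        lv_b = sel["mc_b"].sum() / sel["total_b"].sum()
        d = lv_a - lv_b
        if abs(d) < min_delta:
            continue
        if (sel["total_a"].mean() < min_cov or sel["total_b"].mean() < min_cov):
            continue
        z = stats.norm.isf(np.clip(pvals[run], 1e-300, 1.0) / 2) * sign[run]
        z_comb = z.sum() / np.sqrt(n_cg)
        p_region = float(2 * stats.norm.sf(abs(z_comb)))
        dmrs.append(DMR(contig=str(sel["contig"].iloc[0]),
                        start=int(sel["cg_pos"].min()) - 1,
                        end=int(sel["cg_pos"].max()) + 1,
                        n_cg=n_cg, delta=float(d), p_value=p_region,
                        direction="hyper" if d > 0 else "hypo"))
    return dmrs


def gene_body_levels(table: MethylomeTable, features, context: str = "CG",
                     kind: str = "gene") -> pd.DataFrame:
    """Per-feature weighted body methylation in one context."""
    feats = features.table if isinstance(features, FeatureSet) else features
    feats = feats[feats["kind"] == kind] if "kind" in feats.columns else feats
    df = table.table
    sub = df[_group_mask(df, context)]
    rows = []
    for _, f in feats.iterrows():
        s = sub[(sub["contig"] == f.contig) & (sub["pos"] - 1 >= f.start)
                & (sub["pos"] - 1 < f.end)]
        tot = int(s["total"].sum())
        level = float(s["mc"].sum() / tot) if tot else np.nan
        rows.append((f.id, level, f.get("tpm", np.nan)))
    return pd.DataFrame(rows, columns=["id", "level", "tpm"])


def expression_methylation_correlation(levels, tpm, method: str = "spearman"):
    """Rank (or linear) correlation of body methylation against expression.

    Returns ``(r, n)``; r is NaN when fewer than 3 complete pairs remain or
    either vector is constant. Ties are mid-ranked by scipy.
    """
    levels = np.asarray(levels, dtype=float)
    tpm = np.asarray(tpm, dtype=float)
    ok = ~(np.isnan(levels) | np.isnan(tpm))
    x, y = levels[ok], tpm[ok]
    n = int(x.size)
    if n < 3 or np.std(x) == 0 or np.std(y) == 0:
        return np.nan, n
    if method == "spearman":
        r = float(stats.spearmanr(x, y).statistic)
    elif method == "pearson":
        r = float(stats.pearsonr(x, y).statistic)
    else:
        raise ValueError(f"unknown method {method!r}")
    return r, n
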