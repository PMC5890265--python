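"""Synthetic genomes, methylomes, bisulfite reads, TE families and codon pairs.

Everything downstream of read mapping is exercised against data built here:
a genome with genes and planted retroelement copies (LINE / DIRS / LTR
architectures with target-site duplications and terminal repeats), a truth
methylome with near-saturated CG methylation and low, 3'-biased CH
methylation on transposons, pre-aligned single-end bisulfite reads with an
unmethylated lambda-like spike-in, codon pairs diverged at a known dN/dS,
and transposon-subfamily presence/absence histories on a species tree.

All randomness flows from ``SimulationConfig.seed`` through per-stage
``numpy`` generators, so identical configurations give byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TEFamilySpec",
    "SimulationConfig",
    "SimulatedGenome",
    "PlantedTE",
    "TruthMethylome",
    "AlignedRead",
    "simulate_genome",
    "apply_cg_deamination",
    "simulate_truth_methylome",
    "simulate_bisulfite_reads",
    "simulate_codon_pair_set",
    "simulate_family_history",
    "domain_table_for_elements",
    "write_sam",
    "write_fasta",
    "write_gff3",
    "write_bed",
    "write_expression_tsv",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

# stage tags mixed with the user seed so each op has an independent stream
_STAGE_GENOME = 11
_STAGE_TRUTH = 23
_STAGE_READS = 37
_STAGE_CODON = 53
_STAGE_FAMILY = 71


def _rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stage]))


def _random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=p).tobytes().decode()


def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq.upper()))


# --------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class TEFamilySpec:
    """One retroelement family to plant in the genome.

    ``orf_layout`` lists the ordered ORFs, each as a tuple of Pfam-style
    domain labels (e.g. ``(("DNA_methylase",), ("Exo_endo_phos", "RVT_1"))``
    for a LINE whose first ORF carries the methyltransferase).
    """

    name: str
    architecture: str  # LINE | DIRS | LTR
    orf_layout: tuple = (("RVT_1",),)
    consensus_length: int = 3000
    n_copies: int = 5
    divergence: float = 0.0
    cg_deamination_rate: float = 0.0
    tsd_length: int = 0
    ltr_length: int = 0
    polya: bool = False

    def __post_init__(self):
        if self.architecture not in ("LINE", "DIRS", "LTR"):
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.architecture == "LINE" and (self.ltr_length or not self.tsd_length):
            raise ValueError("LINE families need tsd_length>0 and ltr_length=0")
        if self.architecture in ("DIRS", "LTR") and self.ltr_length <= 0:
            raise ValueError(f"{self.architecture} families need ltr_length>0")
        if self.cg_deamination_rate < 0:
            raise ValueError("cg_deamination_rate must be >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic experiment."""

    seed: int = 0
    genome_length: int = 200_000
    n_genes: int = 20
    te_families: tuple = ()
    cg_level: float = 0.7
    ch_level: float = 0.01
    ch_te_3prime_bias: float = 5.0
    ch_te_tail_fraction: float = 0.25
    heterogeneity: float = 2.0  # beta concentration kappa
    non_conversion: float = 0.005
    coverage: float = 30.0
    read_length: int = 100
    lambda_length: int = 48_502
    symmetric_cg: bool = False
    seq_error: float = 0.0
    n_snvs: int = 0  # planted C->T / G->A variants vs the reference
    gene_length_range: tuple = (1000, 3000)
    expr_meth_coupling: float = 0.0
    main_contig: str = "contig1"
    control_contig: str = "lambda_control"

    def __post_init__(self):
        for name in ("cg_level", "ch_level", "non_conversion", "seq_error"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.ch_te_3prime_bias < 1:
            raise ValueError("ch_te_3prime_bias must be >= 1")
        if self.heterogeneity <= 0:
            raise ValueError("heterogeneity (kappa) must be > 0")
        if self.genome_length < 10 * self.read_length:
            raise ValueError("genome_length must be >= 10 x read_length")
        if isinstance(self.te_families, list):
            object.__setattr__(self, "te_families", tuple(self.te_families))


@dataclass
class PlantedTE:
    """Structural truth for one inserted element copy.

    Coordinates are 0-based half-open. ``start``/``end`` delimit the element
    itself; the TSD copies sit immediately outside. ``repeats``, ``orfs`` and
    ``domains`` are element-relative.
    """

    id: str
    family: str
    architecture: str
    contig: str
    start: int
    end: int
    strand: str
    tsd: str | None
    repeats: list  # (label, rel_start, rel_end)
    orfs: list  # (rel_start, rel_end) including the stop codon
    domains: list  # (label, rel_start, rel_end) nucleotide coords
    polya: bool
    sequence: str


@dataclass
class SimulatedGenome:
    genome: dict  # reference contig -> sequence
    features: pd.DataFrame  # contig,start,end,strand,kind,id,family,tpm
    te_registry: list
    sample_genome: dict  # contigs actually sequenced (SNVs applied)
    snvs: list  # (contig, pos0, ref_base, alt_base)


@dataclass
class TruthMethylome:
    """Per-cytosine true methylation probabilities."""

    table: pd.DataFrame  # contig,pos(1-based),strand,context,p

    def p_arrays(self, genome: dict) -> dict:
        """Per-contig (p_plus, p_minus) arrays indexed by 0-based position."""
        out = {}
        for contig, seq in genome.items():
            L = len(seq)
            out[contig] = (np.full(L, np.nan), np.full(L, np.nan))
        for contig, sub in self.table.groupby("contig", sort=False):
            plus = sub[sub["strand"] == "+"]
            minus = sub[sub["strand"] == "-"]
            out[contig][0][plus["pos"].to_numpy() - 1] = plus["p"].to_numpy()
            out[contig][1][minus["pos"].to_numpy() - 1] = minus["p"].to_numpy()
        return out


@dataclass
class AlignedRead:
    name: str
    contig: str
    start: int  # 0-based leftmost
    reverse: bool
    seq: str


# --------------------------------------------------------------------------
# sequence-level helpers


_STOPS = {"TAA", "TAG", "TGA"}
_NONSTOP = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
            if a + b + c not in _STOPS]


def _random_orf(rng: np.random.Generator, n_codons: int) -> str:
    body = rng.choice(np.array(_NONSTOP), size=n_codons - 1)
    return "ATG" + "".join(body) + "TAA"


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = np.nonzero(rng.random(arr.size) < rate)[0]
    for i in hit:
        cur = arr[i]
        choices = _BASES[_BASES != cur]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def apply_cg_deamination(seq: str, rate: float, seed=None, rng=None) -> str:
    """Convert CG dinucleotides to TG or CA, each independently with ``rate``.

    Models the mutational decay of methylated CpGs: the deamination hits the
    methylated C of one strand, so CG -> TG (plus strand) or CG -> CA
    (minus strand, where the G carries the complementary C).
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate outside [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    if rate == 0:
        return seq
    out = list(seq)
    upper = seq.upper()
    for i in range(len(seq) - 1):
        if upper[i] == "C" and upper[i + 1] == "G" and rng.random() < rate:
            if rng.random() < 0.5:
                out[i] = "T"
            else:
                out[i + 1] = "A"
    return "".join(out)


# --------------------------------------------------------------------------
# genome assembly


def _build_consensus(spec: TEFamilySpec, rng: np.random.Generator):
    """Consensus element sequence plus element-relative structural truth."""
    utr = 150
    spacer = 60
    parts: list[str] = []
    orfs: list[tuple[int, int]] = []
    domains: list[tuple[str, int, int]] = []
    pos = 0

    def _push(s: str):
        nonlocal pos
        parts.append(s)
        pos += len(s)

    repeats: list[tuple[str, int, int]] = []
    rep_a = _random_seq(rng, spec.ltr_length) if spec.ltr_length else ""
    rep_b = _random_seq(rng, spec.ltr_length) if spec.architecture == "DIRS" else ""

    if spec.architecture in ("DIRS", "LTR"):
        repeats.append(("A", pos, pos + len(rep_a)))
        _push(rep_a)
    _push(_random_seq(rng, utr))
    for domain_labels in spec.orf_layout:
        n_codons = 60 + 110 * len(domain_labels)
        orf = _random_orf(rng, n_codons)
        orf_start = pos
        for k, label in enumerate(domain_labels):
            aa_from = 20 + 100 * k
            aa_to = aa_from + 80
            domains.append((label, orf_start + 3 * aa_from, orf_start + 3 * aa_to))
        orfs.append((orf_start, orf_start + len(orf)))
        _push(orf)
        _push(_random_seq(rng, spacer))
    _push(_random_seq(rng, max(0, utr - spacer)))
    if spec.polya:
        _push("A" * 12 + _random_seq(rng, 10))
    if spec.architecture == "DIRS":
        repeats.append(("B", pos, pos + len(rep_b)))
        _push(rep_b)
        repeats.append(("A", pos, pos + len(rep_a)))
        _push(rep_a)
        repeats.append(("B", pos, pos + len(rep_b)))
        _push(rep_b)
    elif spec.architecture == "LTR":
        repeats.append(("A", pos, pos + len(rep_a)))
        _push(rep_a)
    consensus = "".join(parts)
    return consensus, repeats, orfs, domains


def simulate_genome(config: SimulationConfig) -> SimulatedGenome:
    """Assemble the reference: one main contig with genes and TE copies plus
    an unmethylated spike-in contig.

    Features are laid out left to right in shuffled order with multinomially
    distributed gaps, so placement is uniform given the total feature length;
    an explicit error is raised when the features cannot fit.
    """
    rng = _rng(config.seed, _STAGE_GENOME)

    blocks = []  # (kind, length, payload)
    for g in range(config.n_genes):
        lo, hi = config.gene_length_range
        glen = int(rng.integers(lo, hi + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        tpm = float(np.round(rng.lognormal(1.0, 1.5), 3))
        blocks.append(("gene", glen, {"id": f"gene{g + 1}", "strand": strand,
                                      "tpm": tpm}))

    registry: list[PlantedTE] = []
    for spec in config.te_families:
        consensus, repeats, orfs, domains = _build_consensus(spec, rng)
        for c in range(spec.n_copies):
            copy_seq = _mutate(consensus, spec.divergence, rng)
            if spec.cg_deamination_rate > 0:
                copy_seq = apply_cg_deamination(copy_seq, spec.cg_deamination_rate,
                                                rng=rng)
            tsd = _random_seq(rng, spec.tsd_length) if spec.tsd_length else None
            tpm = float(np.round(rng.lognormal(0.0, 1.0), 3)) \
                if rng.random() < 0.6 else 0.0
            te = PlantedTE(
                id=f"{spec.name}_{c + 1}", family=spec.name,
                architecture=spec.architecture, contig=config.main_contig,
                start=-1, end=-1, strand="+", tsd=tsd,
                repeats=list(repeats), orfs=list(orfs), domains=list(domains),
                polya=spec.polya, sequence=copy_seq)
            blocks.append(("te", len(copy_seq) + 2 * spec.tsd_length,
                           {"te": te, "tpm": tpm, "tsd": tsd}))

    order = rng.permutation(len(blocks))
    blocks = [blocks[i] for i in order]
    total = sum(b[1] for b in blocks)
    free = config.genome_length - total
    if free < 0:
        raise ValueError(
            f"infeasible packing: features need {total} bp but genome_length "
            f"is {config.genome_length}")
    gaps = rng.multinomial(free, np.full(len(blocks) + 1, 1 / (len(blocks) + 1)))

    parts = []
    rows = []
    pos = 0

    def _emit(s: str):
        nonlocal pos
        parts.append(s)
        pos += len(s)

    for i, (kind, length, payload) in enumerate(blocks):
        _emit(_random_seq(rng, int(gaps[i])))
        if kind == "gene":
            start = pos
            _emit(_random_seq(rng, length))
            rows.append((config.main_contig, start, pos, payload["strand"],
                         "gene", payload["id"], ".", payload["tpm"]))
        else:
            te: PlantedTE = payload["te"]
            tsd = payload["tsd"] or ""
            _emit(tsd)
            te.start = pos
            _emit(te.sequence)
            te.end = pos
            _emit(tsd)
            registry.append(te)
            rows.append((config.main_contig, te.start, te.end, te.strand,
                         "TE", te.id, te.family, payload["tpm"]))
    _emit(_random_seq(rng, int(gaps[-1])))
    main = "".join(parts)

    lam = _random_seq(rng, config.lambda_length)
    genome = {config.main_contig: main, config.control_contig: lam}

    features = pd.DataFrame(
        rows, columns=["contig", "start", "end", "strand", "kind", "id",
                       "family", "tpm"]).sort_values(
        ["contig", "start"]).reset_index(drop=True)

    snvs = []
    sample = genome
    if config.n_snvs > 0:
        arr = np.frombuffer(main.encode(), dtype="S1").copy()
        c_pos = np.nonzero((arr == b"C") | (arr == b"G"))[0]
        chosen = rng.choice(c_pos, size=min(config.n_snvs, c_pos.size),
                            replace=False)
        for i in sorted(int(x) for x in chosen):
            ref = arr[i].decode()
            alt = "T" if ref == "C" else "A"
            arr[i] = alt.encode()
            snvs.append((config.main_contig, i, ref, alt))
        sample = dict(genome)
        sample[config.main_contig] = arr.tobytes().decode()

    return SimulatedGenome(genome=genome, features=features,
                           te_registry=registry, sample_genome=sample,
                           snvs=snvs)


# --------------------------------------------------------------------------
# truth methylome


def _context_arrays(seq: str):
    """(is_c_plus, is_c_minus, context_plus, context_minus) over a contig.

    Context codes: 0=CG, 1=CHG, 2=CHH, 3=undefined (truncated or N window).
    """
    arr = np.frombuffer(seq.upper().encode(), dtype="S1")
    L = arr.size
    is_c = arr == b"C"
    is_g = arr == b"G"
    is_n = arr == b"N"

    nxt_g = np.zeros(L, bool)
    nxt_g[:-1] = is_g[1:]
    nxt2_g = np.zeros(L, bool)
    nxt2_g[:-2] = is_g[2:]
    nxt_n = np.ones(L, bool)
    nxt_n[:-1] = is_n[1:]
    nxt2_n = np.ones(L, bool)
    nxt2_n[:-2] = is_n[2:]

    ctx_plus = np.full(L, 2, dtype=np.int8)
    ctx_plus[nxt2_g] = 1
    ctx_plus[nxt_g] = 0
    bad = nxt_n | (~nxt_g & nxt2_n)
    ctx_plus[bad] = 3

    prv_c = np.zeros(L, bool)
    prv_c[1:] = is_c[:-1]
    prv2_c = np.zeros(L, bool)
    prv2_c[2:] = is_c[:-2]
    prv_n = np.ones(L, bool)
    prv_n[1:] = is_n[:-1]
    prv2_n = np.ones(L, bool)
    prv2_n[2:] = is_n[:-2]

    ctx_minus = np.full(L, 2, dtype=np.int8)
    ctx_minus[prv2_c] = 1
    ctx_minus[prv_c] = 0
    bad = prv_n | (~prv_c & prv2_n)
    ctx_minus[bad] = 3
    return is_c, is_g, ctx_plus, ctx_minus


_CTX_NAMES = np.array(["CG", "CHG", "CHH", "."])


def simulate_truth_methylome(genome: dict, features: pd.DataFrame,
                             config: SimulationConfig) -> TruthMethylome:
    """Draw per-site true methylation probabilities.

    p_i ~ Beta(kappa*m, kappa*(1-m)) with m the context target: ``cg_level``
    at CG sites and ``ch_level`` elsewhere, the latter multiplied by
    ``ch_te_3prime_bias`` (mean capped at 1) over the 3'-most
    ``ch_te_tail_fraction`` of each TE. The spike-in contig is fully
    unmethylated. With ``symmetric_cg`` the two strands of a CG share one
    draw; by default they are independent, reflecting per-cell stochastic
    gain rather than maintenance of palindromic pairs.
    """
    rng = _rng(config.seed, _STAGE_TRUTH)
    kappa = config.heterogeneity
    frames = []
    te_feats = features[features["kind"] == "TE"]
    for contig, seq in genome.items():
        is_c, is_g, ctx_plus, ctx_minus = _context_arrays(seq)
        L = len(seq)
        ch_mean = np.full(L, config.ch_level)
        if contig != config.control_contig:
            for _, te in te_feats[te_feats["contig"] == contig].iterrows():
                length = te.end - te.start
                tail = int(round(length * config.ch_te_tail_fraction))
                if te.strand == "-":
                    sl = slice(te.start, te.start + tail)
                else:
                    sl = slice(te.end - tail, te.end)
                ch_mean[sl] = min(1.0, config.ch_level * config.ch_te_3prime_bias)

        gene_shift = np.zeros(L)
        if config.expr_meth_coupling > 0 and contig != config.control_contig:
            genes = features[(features["kind"] == "gene")
                             & (features["contig"] == contig)]
            if len(genes):
                ranks = genes["tpm"].rank(pct=True)
                for (_, g), r in zip(genes.iterrows(), ranks):
                    gene_shift[g.start:g.end] = \
                        config.expr_meth_coupling * (r - 0.5)

        for strand, mask, ctx in (("+", is_c, ctx_plus), ("-", is_g, ctx_minus)):
            pos0 = np.nonzero(mask)[0]
            c = ctx[pos0]
            if contig == config.control_contig:
                p = np.zeros(pos0.size)
            else:
                m = np.where(c == 0, config.cg_level, ch_mean[pos0])
                m = np.clip(m + np.where(c == 0, gene_shift[pos0], 0.0),
                            0.0, 1.0)
                p = np.zeros(pos0.size)
                mid = (m > 0) & (m < 1)
                p[mid] = rng.beta(kappa * m[mid], kappa * (1 - m[mid]))
                p[m >= 1] = 1.0
            frames.append(pd.DataFrame({
                "contig": contig, "pos": pos0 + 1, "strand": strand,
                "context": _CTX_NAMES[c], "p": p}))

    table = pd.concat(frames, ignore_index=True)
    table = table.sort_values(["contig", "pos", "strand"]).reset_index(drop=True)

    if config.symmetric_cg:
        # copy the plus-strand draw onto the paired minus-strand C (pos+1)
        plus = table[(table["strand"] == "+") & (table["context"] == "CG")]
        key = pd.MultiIndex.from_arrays(
            [plus["contig"], plus["pos"] + 1])
        lut = pd.Series(plus["p"].to_numpy(), index=key)
        minus_mask = (table["strand"] == "-") & (table["context"] == "CG")
        idx = pd.MultiIndex.from_arrays(
            [table.loc[minus_mask, "contig"], table.loc[minus_mask, "pos"]])
        table.loc[minus_mask, "p"] = lut.reindex(idx).to_numpy()
    return TruthMethylome(table=table)


# --------------------------------------------------------------------------
# bisulfite reads


def simulate_bisulfite_reads(genome: dict, truth: TruthMethylome,
                             config: SimulationConfig) -> list:
    """Emit pre-aligned single-end bisulfite reads.

    Each read is one molecule from one strand. On the original-top-strand
    reads every plus-strand cytosine reads C with probability p_i (else T);
    on bottom-strand reads, stored in forward orientation, every minus-strand
    cytosine (a reference G) reads G (methylated) or A (converted). Failed
    conversions turn unmethylated outcomes back into the methylated call with
    probability ``non_conversion``. Placement is uniform.
    """
    if config.coverage <= 0:
        raise ValueError("coverage must be > 0")
    rng = _rng(config.seed, _STAGE_READS)
    parr = truth.p_arrays(genome)
    reads: list[AlignedRead] = []
    rl = config.read_length
    for contig in genome:
        seq = genome[contig]
        L = len(seq)
        if L < rl:
            continue
        n_reads = int(round(config.coverage * L / rl))
        starts = rng.integers(0, L - rl + 1, size=n_reads)
        strands = rng.random(n_reads) < 0.5
        p_plus, p_minus = parr[contig]
        arr = np.frombuffer(seq.upper().encode(), dtype="S1")
        for r in range(n_reads):
            s = int(starts[r])
            sub = arr[s:s + rl].copy()
            if strands[r]:  # bottom strand: G stays G if methylated, else A
                p = p_minus[s:s + rl]
                sites = np.nonzero(~np.isnan(p))[0]
                meth = rng.random(sites.size) < p[sites]
                meth |= rng.random(sites.size) < config.non_conversion
                sub[sites[~meth]] = b"A"
            else:  # top strand: C stays C if methylated, else T
                p = p_plus[s:s + rl]
                sites = np.nonzero(~np.isnan(p))[0]
                meth = rng.random(sites.size) < p[sites]
                meth |= rng.random(sites.size) < config.non_conversion
                sub[sites[~meth]] = b"T"
            if config.seq_error > 0:
                errs = np.nonzero(rng.random(rl) < config.seq_error)[0]
                for i in errs:
                    sub[i] = rng.choice(_BASES[_BASES != sub[i]])
            reads.append(AlignedRead(
                name=f"{contig}_read{r + 1}", contig=contig, start=s,
                reverse=bool(strands[r]), seq=sub.tobytes().decode()))
    return reads


def write_sam(reads: list, genome: dict, path: str) -> None:
    """Write reads as a standard-conformant SAM file (MAPQ 60, ungapped)."""
    import pysam

    header = {"HD": {"VN": "1.6", "SO": "unsorted"},
              "SQ": [{"SN": name, "LN": len(seq)}
                     for name, seq in genome.items()]}
    with pysam.AlignmentFile(path, "wh", header=header) as out:
        hdr = out.header
        for rd in reads:
            a = pysam.AlignedSegment(hdr)
            a.query_name = rd.name
            a.query_sequence = rd.seq
            a.flag = 16 if rd.reverse else 0
            a.reference_id = hdr.get_tid(rd.contig)
            a.reference_start = rd.start
            a.mapping_quality = 60
            a.cigartuples = [(0, len(rd.seq))]
            a.query_qualities = pysam.qualitystring_to_array("I" * len(rd.seq))
            out.write(a)


# --------------------------------------------------------------------------
# codon evolution


_CODON_TABLE = None


def _codon_aa():
    global _CODON_TABLE
    if _CODON_TABLE is None:
        from Bio.Data.CodonTable import standard_dna_table

        t = dict(standard_dna_table.forward_table)
        for stop in standard_dna_table.stop_codons:
            t[stop] = "*"
        _CODON_TABLE = t
    return _CODON_TABLE


def simulate_codon_pair_set(n_pairs: int, codons: int, omega: float,
                            ts_tv: float = 2.0, seed: int = 0,
                            branch_length: float = 0.15) -> list:
    """Pairs of coding sequences diverged from a common ancestor.

    Point mutations are proposed along two independent branches
    (``branch_length`` expected proposals per nucleotide site per branch)
    with transition:transversion weighting ``ts_tv``; synonymous proposals
    are always accepted, nonsynonymous ones with probability ``omega``, and
    stop codons are never introduced, so the realised dN/dS tracks ``omega``.
    """
    if omega <= 0:
        raise ValueError("omega must be > 0")
    if codons < 50:
        raise ValueError("use at least 50 codons")
    rng = _rng(seed, _STAGE_CODON)
    aa = _codon_aa()
    transitions = {"A": "G", "G": "A", "C": "T", "T": "C"}
    pairs = []
    for _ in range(n_pairs):
        anc = [str(c) for c in rng.choice(np.array(_NONSTOP), size=codons)]
        out = []
        for _branch in range(2):
            seqc = list(anc)
            n_prop = rng.poisson(branch_length * 3 * codons)
            for _m in range(n_prop):
                site = int(rng.integers(0, 3 * codons))
                ci, off = divmod(site, 3)
                codon = seqc[ci]
                cur = codon[off]
                if rng.random() < ts_tv / (ts_tv + 1):
                    new = transitions[cur]
                else:
                    tv = [b for b in "ACGT" if b != cur and b != transitions[cur]]
                    new = str(rng.choice(np.array(tv)))
                cand = codon[:off] + new + codon[off + 1:]
                if aa[cand] == "*":
                    continue
                if aa[cand] != aa[codon] and rng.random() >= omega:
                    continue
                seqc[ci] = cand
            out.append("".join(seqc))
        pairs.append((out[0], out[1]))
    return pairs


# --------------------------------------------------------------------------
# subfamily gain/loss histories


def simulate_family_history(tree, n_subfamilies: int, loss_prob: float,
                            seed: int = 0):
    """Single-gain / multiple-loss histories on a rooted species tree.

    Each subfamily gains exactly once at a uniformly sampled node and is then
    lost independently on each descendant edge with ``loss_prob`` (a lost
    lineage stays lost). Returns the tip presence/absence matrix and the true
    event list ``{gain: node_label, losses: [child_labels]}`` per subfamily.
    """
    import dendropy

    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")
    if tree.seed_node is None:
        raise ValueError("tree must be rooted")
    rng = _rng(seed, _STAGE_FAMILY)

    nodes = list(tree.preorder_node_iter())
    for i, n in enumerate(nodes):
        if n.taxon is None and not getattr(n, "label", None):
            n.label = f"n{i}"

    def node_name(n):
        return n.taxon.label if n.taxon else n.label

    tips = [node_name(l) for l in tree.leaf_node_iter()]
    rows = []
    events = []
    for s in range(n_subfamilies):
        gain = nodes[int(rng.integers(0, len(nodes)))]
        present = set()
        losses = []

        def _descend(node, alive):
            if not alive:
                return
            if node.is_leaf():
                present.add(node_name(node))
                return
            for child in node.child_nodes():
                if rng.random() < loss_prob:
                    losses.append(node_name(child))
                else:
                    _descend(child, True)

        if gain.is_leaf():
            present.add(node_name(gain))
        else:
            _descend(gain, True)
        rows.append([1 if t in present else 0 for t in tips])
        events.append({"subfamily": f"sf{s + 1}", "gain": node_name(gain),
                       "losses": losses})
    matrix = pd.DataFrame(rows, columns=tips,
                          index=[f"sf{s + 1}" for s in range(n_subfamilies)])
    return matrix, events


# --------------------------------------------------------------------------
# bridges and writers


def domain_table_for_elements(registry: list, orfs_by_element: dict) -> pd.DataFrame:
    """Domain-hit table (domtblout-style columns) from planted domain truth.

    Stands in for a profile-HMM search: each planted domain interval is
    assigned to the detected ORF that contains it, with envelope coordinates
    in amino acids on that ORF's protein and a nominal e-value.
    """
    rows = []
    for te in registry:
        orfs = orfs_by_element.get(te.id, [])
        for label, dstart, dend in te.domains:
            for orf in orfs:
                if orf.strand == "+" and orf.start <= dstart and dend <= orf.end:
                    aa_from = (dstart - orf.start) // 3 + 1
                    aa_to = (dend - orf.start) // 3
                    rows.append((orf.id, label, 1e-30, aa_from, aa_to))
                    break
    return pd.DataFrame(rows, columns=["target_name", "query_name", "evalue",
                                       "env_from", "env_to"])


def write_fasta(seqs: dict, path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_gff3(features: pd.DataFrame, path: str) -> None:
    """1-based inclusive feature table."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, r in features.iterrows():
            kind = "gene" if r.kind == "gene" else "repeat_region"
            attrs = f"ID={r.id}"
            if r.family and r.family != ".":
                attrs += f";family={r.family}"
            fh.write("\t".join([r.contig, "temeth-sim", kind, str(r.start + 1),
                                str(r.end), ".", r.strand, ".", attrs]) + "\n")


def write_bed(features: pd.DataFrame, path: str) -> None:
    """0-based half-open feature table."""
    with open(path, "w") as fh:
        for _, r in features.iterrows():
            fh.write("\t".join([r.contig, str(r.start), str(r.end), r.id, "0",
                                r.strand]) + "\n")


def write_expression_tsv(features: pd.DataFrame, path: str) -> None:
    features[["id", "tpm"]].to_csv(path, sep="\t", index=False)


def write_truth_tsv(truth: TruthMethylome, path: str) -> None:
    truth.table.to_csv(path, sep="\t", index=False, float_format="%.6g")
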