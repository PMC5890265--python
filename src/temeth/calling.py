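"""Per-cytosine methylation calls from aligned bisulfite reads.

The pileup walks reads once and accumulates strand-separated base counts, then
emits one record per reference cytosine on each strand: methylated calls (C on
top-strand reads, G on bottom-strand reads in forward orientation),
informative totals (C+T and G+A respectively), and the opposite-strand
genotype support used to drop C->T variants masquerading as unmethylated
cytosines. Context (CG / CHG / CHH, H any base but G) is taken from the
reference only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import _context_arrays, _CTX_NAMES

log = logging.getLogger(__name__)

__all__ = [
    "MethylomeTable",
    "pileup_cytosines",
    "assign_context",
    "genotype_filter",
    "estimate_nonconversion",
    "adjust_level",
    "write_methylome",
    "read_methylome",
]

_COLUMNS = ["contig", "pos", "strand", "context", "dinuc", "mc", "total",
            "opposite_g_fraction", "opposite_cov"]


@dataclass
class MethylomeTable:
    """Ordered per-cytosine call set plus library metadata.

    ``table`` columns: contig, pos (1-based, forward strand), strand,
    context, dinuc (the strandwise next base, for CA/CT/CC/CG reporting),
    mc, total, opposite_g_fraction, opposite_cov. Sorted by
    (contig, pos, strand) with unique keys.
    """

    table: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.table)

    def copy(self) -> "MethylomeTable":
        return MethylomeTable(self.table.copy(), dict(self.metadata))


_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASE_LUT = np.full(256, -1, dtype=np.int8)
for _b, _i in _BASE_IDX.items():
    _BASE_LUT[ord(_b)] = _i
    _BASE_LUT[ord(_b.lower())] = _i


def _load_genome(genome) -> dict:
    if isinstance(genome, dict):
        return genome
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(genome), "fasta")}


def pileup_cytosines(alignments, genome, min_mapq: int = 10,
                     exclude_contigs: tuple = ()) -> MethylomeTable:
    """Pile up strand-aware C/T (and G/A) calls over every reference cytosine.

    ``alignments`` is a SAM/BAM path or an open ``pysam.AlignmentFile``;
    ``genome`` a FASTA path or ``{name: sequence}`` dict. Duplicate-flagged,
    secondary, supplementary, unmapped and low-MAPQ reads are skipped.
    ``exclude_contigs`` supports organelle/plastid blacklisting.
    """
    import pysam

    genome = _load_genome(genome)
    own = isinstance(alignments, str)
    af = pysam.AlignmentFile(alignments, check_sq=False) if own else alignments

    for contig in af.references:
        if contig not in genome and contig not in exclude_contigs:
            raise ValueError(f"alignment contig {contig!r} missing from reference")

    # per-contig (L, 8) counts: columns 0-3 forward A/C/G/T, 4-7 reverse
    counts = {c: np.zeros((len(s), 8), dtype=np.int32)
              for c, s in genome.items() if c not in exclude_contigs}
    n_used = 0
    for read in af:
        if (read.is_unmapped or read.is_secondary or read.is_supplementary
                or read.is_duplicate or read.mapping_quality < min_mapq):
            continue
        contig = read.reference_name
        if contig not in counts:
            continue
        mat = counts[contig]
        off = 4 if read.is_reverse else 0
        seq = read.query_sequence
        ct = read.cigartuples
        if ct is not None and len(ct) == 1 and ct[0][0] == 0:
            # ungapped: vectorised accumulation
            code = _BASE_LUT[np.frombuffer(seq.encode(), np.uint8)]
            valid = np.nonzero(code >= 0)[0]
            np.add.at(mat, (read.reference_start + valid,
                            off + code[valid].astype(np.intp)), 1)
        else:
            for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                b = _BASE_IDX.get(seq[qpos])
                if b is not None:
                    mat[rpos, off + b] += 1
        n_used += 1
    if own:
        af.close()
    if n_used == 0:
        warnings.warn("no usable reads; returning empty methylome table")
        return MethylomeTable(pd.DataFrame(columns=_COLUMNS))

    frames = []
    for contig, seq in genome.items():
        if contig in exclude_contigs:
            continue
        mat = counts[contig]
        arr = np.frombuffer(seq.upper().encode(), dtype="S1")
        is_c, is_g, ctx_plus, ctx_minus = _context_arrays(seq)

        # forward-strand cytosines: informative reads are top-strand (C/T)
        pos0 = np.nonzero(is_c)[0]
        mc = mat[pos0, 0 + _BASE_IDX["C"]]
        total = mc + mat[pos0, 0 + _BASE_IDX["T"]]
        opp = mat[pos0, 4:8]
        opp_cov = opp.sum(axis=1)
        # a true G on the bottom strand is stored as C in forward orientation
        with np.errstate(invalid="ignore"):
            gfrac = np.where(opp_cov > 0,
                             opp[:, _BASE_IDX["C"]] / np.maximum(opp_cov, 1),
                             np.nan)
        nxt = np.full(pos0.size, "N")
        ok = pos0 + 1 < len(seq)
        nxt[ok] = arr[pos0[ok] + 1].astype("U1")
        frames.append(pd.DataFrame({
            "contig": contig, "pos": pos0 + 1, "strand": "+",
            "context": _CTX_NAMES[ctx_plus[pos0]], "dinuc": nxt,
            "mc": mc, "total": total, "opposite_g_fraction": gfrac,
            "opposite_cov": opp_cov}))

        # reverse-strand cytosines (reference G): bottom-strand reads, G/A
        pos0 = np.nonzero(is_g)[0]
        mc = mat[pos0, 4 + _BASE_IDX["G"]]
        total = mc + mat[pos0, 4 + _BASE_IDX["A"]]
        opp = mat[pos0, 0:4]
        opp_cov = opp.sum(axis=1)
        with np.errstate(invalid="ignore"):
            gfrac = np.where(opp_cov > 0,
                             opp[:, _BASE_IDX["G"]] / np.maximum(opp_cov, 1),
                             np.nan)
        prv = np.full(pos0.size, "N")
        ok = pos0 - 1 >= 0
        comp = {b"A": "T", b"C": "G", b"G": "C", b"T": "A"}
        prv[ok] = [comp.get(bytes(b), "N") for b in arr[pos0[ok] - 1]]
        frames.append(pd.DataFrame({
            "contig": contig, "pos": pos0 + 1, "strand": "-",
            "context": _CTX_NAMES[ctx_minus[pos0]], "dinuc": prv,
            "mc": mc, "total": total, "opposite_g_fraction": gfrac,
            "opposite_cov": opp_cov}))

    table = pd.concat(frames, ignore_index=True)
    table = table.sort_values(["contig", "pos", "strand"],
                              kind="mergesort").reset_index(drop=True)
    return MethylomeTable(table)


def assign_context(genome, contig: str, position: int, strand: str) -> str:
    """Context of the cytosine at 1-based ``position`` on ``strand``.

    CG if the strandwise next base is G, CHG if the base after next is G,
    else CHH; returns '.' when the window is truncated or contains N.
    """
    genome = _load_genome(genome)
    seq = genome[contig].upper()
    i = position - 1
    if strand == "+":
        if seq[i] != "C":
            raise ValueError(f"{contig}:{position}+ is {seq[i]}, not C")
        window = seq[i:i + 3]
    else:
        if seq[i] != "G":
            raise ValueError(f"{contig}:{position}- is {seq[i]}, not C "
                             "(reference G expected)")
        window = "".join({"A": "T", "C": "G", "G": "C", "T": "A"}.get(b, "N")
                         for b in reversed(seq[max(0, i - 2):i + 1]))
    if len(window) >= 2 and window[1] == "G":
        return "CG"
    if len(window) < 2 or window[1] == "N":
        return "."
    if len(window) >= 3 and window[2] == "G":
        return "CHG"
    if len(window) < 3 or window[2] == "N":
        return "."
    return "CHH"


def genotype_filter(table: MethylomeTable, min_opposite_g: float = 0.8,
                    min_opposite_cov: int = 3) -> MethylomeTable:
    """Drop sites whose opposite strand contradicts a C/G genotype.

    A record is removed when opposite-strand coverage reaches
    ``min_opposite_cov`` but the fraction of reads supporting the paired G is
    below ``min_opposite_g`` — the site is treated as a C->T variant, not an
    unmethylated cytosine.
    """
    df = table.table
    bad = ((df["opposite_cov"] >= min_opposite_cov)
           & (df["opposite_g_fraction"] < min_opposite_g))
    removed = int(bad.sum())
    log.info("genotype filter removed %d of %d records", removed, len(df))
    out = table.copy()
    out.table = df[~bad].reset_index(drop=True)
    out.metadata["genotype_filtered"] = removed
    return out


def estimate_nonconversion(table: MethylomeTable,
                           control_contig: str = "lambda_control") -> float:
    """Bisulfite non-conversion rate: mC calls / all C calls on the spike-in."""
    df = table.table
    sub = df[df["contig"] == control_contig]
    if sub.empty:
        raise ValueError(f"control contig {control_contig!r} absent from table")
    total = int(sub["total"].sum())
    rate = float(sub["mc"].sum() / total) if total else float("nan")
    table.metadata["non_conversion"] = rate
    table.metadata["control_contig"] = control_contig
    return rate


def adjust_level(level: float, nonconv: float) -> float:
    """Correct a methylation level for bisulfite non-conversion."""
    if nonconv >= 1:
        raise ValueError("non-conversion rate must be < 1")
    return max(0.0, (level - nonconv) / (1.0 - nonconv))


def write_methylome(table: MethylomeTable, path: str) -> None:
    with open(path, "w") as fh:
        for k, v in sorted(table.metadata.items()):
            fh.write(f"##{k}={v}\n")
        table.table.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def read_methylome(path: str) -> MethylomeTable:
    meta = {}
    skip = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("##"):
                break
            key, _, val = line[2:].rstrip("\n").partition("=")
            try:
                meta[key] = float(val) if "." in val or "e" in val else val
            except ValueError:
                meta[key] = val
            skip += 1
    try:
        df = pd.read_csv(path, sep="\t", skiprows=skip,
                         dtype={"contig": str, "strand": str, "context": str,
                                "dinuc": str})
    except Exception as exc:  # pragma: no cover - pandas reports the line
        raise ValueError(f"malformed methylome file {path}: {exc}") from exc
    if df.empty:
        return MethylomeTable(pd.DataFrame(columns=_COLUMNS), meta)
    missing = {"contig", "pos", "strand", "mc", "total"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if not df[["contig", "pos", "strand"]].equals(
            df.sort_values(["contig", "pos", "strand"],
                           kind="mergesort")[["contig", "pos", "strand"]]):
        warnings.warn(f"{path}: rows out of order; sorting")
        df = df.sort_values(["contig", "pos", "strand"],
                            kind="mergesort").reset_index(drop=True)
    return MethylomeTable(df, meta)
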