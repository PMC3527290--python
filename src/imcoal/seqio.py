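"""Alignment input and column symbolization.

The model reads a pairwise alignment of one haploid genome per species and
reduces every column to IDENTICAL, DIFFERENT or MISSING.  Two input
formats are supported: a FASTA file with exactly two aligned, equal-length
records, and MAF blocks projected onto a chosen species pair (gaps between
blocks become MISSING runs so coordinates are preserved).  Coordinates in
all outputs are 0-based, half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from Bio import AlignIO, SeqIO

from .symbols import DIFFERENT, IDENTICAL, MISSING

__all__ = [
    "read_pair_fasta",
    "read_maf_pair",
    "symbolize",
    "write_pair_fasta",
    "write_posterior_bed",
    "save_matrix_tsv",
]

log = logging.getLogger(__name__)

_VALID = frozenset(b"ACGT")


def symbolize(
    seq1: str | bytes,
    seq2: str | bytes,
    fold_softmask: bool = True,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Reduce two aligned sequences to the column-symbol alphabet.

    Both bases in {A,C,G,T} and equal -> IDENTICAL; unequal -> DIFFERENT;
    anything else (N, gap, masked) -> MISSING.  Lowercase (soft-masked)
    bases are folded to uppercase by default; with ``fold_softmask=False``
    they are treated as MISSING.  ``mask`` optionally forces positions to
    MISSING (e.g. bases below a quality threshold computed upstream).
    """
    a = np.frombuffer(seq1.encode() if isinstance(seq1, str) else bytes(seq1), dtype=np.uint8)
    b = np.frombuffer(seq2.encode() if isinstance(seq2, str) else bytes(seq2), dtype=np.uint8)
    if len(a) != len(b):
        raise ValueError(f"aligned sequences differ in length ({len(a)} vs {len(b)})")
    if fold_softmask:
        a = np.where((a >= ord("a")) & (a <= ord("z")), a - 32, a)
        b = np.where((b >= ord("a")) & (b <= ord("z")), b - 32, b)
    valid = np.isin(a, list(_VALID)) & np.isin(b, list(_VALID))
    out = np.where(a == b, IDENTICAL, DIFFERENT).astype(np.int8)
    out[~valid] = MISSING
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if len(mask) != len(out):
            raise ValueError("mask length does not match the alignment")
        out[mask] = MISSING
    return out


def read_pair_fasta(path, fold_softmask: bool = True) -> np.ndarray:
    """Column symbols from a FASTA file with exactly two aligned records."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 2:
        raise ValueError(f"expected exactly 2 FASTA records, found {len(records)}")
    return symbolize(str(records[0].seq), str(records[1].seq), fold_softmask)


def read_maf_pair(
    path,
    species1: str,
    species2: str,
    region_length: int | None = None,
    fold_softmask: bool = True,
) -> np.ndarray:
    """Column symbols for one species pair projected from MAF blocks.

    Coordinates follow ``species1`` (the reference of the projection):
    alignment columns where the reference has a gap are dropped, and
    reference positions not covered by any block containing both species
    are MISSING.  Minus-strand reference blocks are reverse-complemented
    onto the forward orientation.  ``region_length`` sets the output
    length (defaults to the reference source size declared in the MAF).
    """
    out = None
    src_size = None
    n_used = 0
    for block in AlignIO.parse(str(path), "maf"):
        recs = {}
        for rec in block:
            sp = rec.id.split(".")[0]
            recs.setdefault(sp, rec)
        if species1 not in recs or species2 not in recs:
            continue
        r1, r2 = recs[species1], recs[species2]
        ann = r1.annotations
        if src_size is None:
            src_size = int(ann.get("srcSize", 0))
            L = region_length if region_length is not None else src_size
            if L <= 0:
                raise ValueError("cannot determine region length from MAF; pass region_length")
            out = np.full(L, MISSING, dtype=np.int8)
        s1 = str(r1.seq)
        s2 = str(r2.seq)
        if ann.get("strand", 1) == -1:
            s1 = _revcomp(s1)
            s2 = _revcomp(s2)
            start = int(ann["srcSize"]) - int(ann["start"]) - int(ann["size"])
        else:
            start = int(ann["start"])
        keep = [i for i, c in enumerate(s1) if c != "-"]
        cols = symbolize("".join(s1[i] for i in keep), "".join(s2[i] for i in keep), fold_softmask)
        end = start + len(cols)
        if end > len(out):
            raise ValueError("MAF block extends past the declared region length")
        out[start:end] = cols
        n_used += 1
    if out is None:
        raise ValueError(f"no MAF block contains both {species1} and {species2}")
    if n_used == 0 or not np.any(out != MISSING):
        log.warning("requested species pair has no informative overlap; all-MISSING output")
    return out


_COMP = str.maketrans("ACGTacgtNn-", "TGCAtgcaNn-")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def write_pair_fasta(path, seq1: str, seq2: str, names=("seq1", "seq2")) -> None:
    with open(path, "w") as fh:
        for name, seq in zip(names, (seq1, seq2)):
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def save_matrix_tsv(path, matrix, row_labels=None, col_labels=None) -> None:
    """Debug export of a model matrix (J, T, interval matrices, emissions)
    as labelled TSV."""
    matrix = np.asarray(matrix)
    with open(path, "w") as fh:
        if col_labels is not None:
            fh.write("\t" + "\t".join(str(c) for c in col_labels) + "\n")
        for i, row in enumerate(matrix):
            label = str(row_labels[i]) if row_labels is not None else str(i)
            fh.write(label + "\t" + "\t".join(f"{v:.12g}" for v in row) + "\n")


def write_posterior_bed(path, track, chrom: str = "seq", offset: int = 0) -> None:
    """Posterior-mean TMRCA track as BED-like TSV: chrom, start, end,
    mean TMRCA (substitutions/site), MAP hidden interval.  Adjacent
    positions with equal MAP state and near-equal mean are merged."""
    tm = track.tmrca
    mp = track.map_state
    if tm is None:
        raise ValueError("decode with interval means to export a TMRCA track")
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tmean_tmrca\tmap_interval\n")
        start = 0
        for i in range(1, len(mp) + 1):
            if i == len(mp) or mp[i] != mp[start] or abs(tm[i] - tm[start]) > 1e-12:
                fh.write(
                    f"{chrom}\t{offset + start}\t{offset + i}\t{tm[start]:.8g}\t{int(mp[start])}\n"
                )
                start = i
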