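"""Canonical k-mer extraction, read-set counting, and reference indexing.

k-mers are packed into 2-bit-per-base integer codes (A=0 < C=1 < G=2 < T=3),
so numeric order on codes coincides with lexicographic order on strings and
the canonical form (the lexicographically smaller of a k-mer and its reverse
complement) is a vectorized element-wise minimum.  Counting is exact: no
probabilistic filters, no maximum-count saturation.  k-mer windows containing
an ambiguous base (N) are skipped in reads and excluded from the reference
index and from the position total N.
"""
from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Optional, Tuple

import numpy as np

from .sequence_io import SequenceRecord

__all__ = [
    "canonical",
    "reverse_complement",
    "KmerCountTable",
    "ReferenceIndex",
    "count_reads",
    "index_reference",
    "restrict_to_reference",
    "save_table",
    "load_table",
]

MAX_K = 31  # codes are packed into uint64 (2 bits/base)

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
    _ENCODE[_b + 32] = _i  # lowercase
_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCATGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(kmer: str, k: Optional[int] = None) -> Optional[str]:
    """Canonical form of a k-mer: the lexicographically smaller of the k-mer
    and its reverse complement (A < C < G < T).

    Returns None if the k-mer contains any character outside {A,C,G,T}.
    Raises if an expected length ``k`` is given and does not match.
    """
    if k is not None and len(kmer) != k:
        raise ValueError(f"expected k-mer of length {k}, got {len(kmer)}")
    kmer = kmer.upper()
    if set(kmer) - set("ACGT"):
        return None
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


def encode(seq: str) -> np.ndarray:
    """Encode a sequence as uint8 over {0..3}=ACGT, 4=anything else."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(arr: np.ndarray) -> str:
    return _DECODE[arr].tobytes().decode("ascii")


def _pack_codes(arr: np.ndarray, k: int) -> np.ndarray:
    """2-bit-pack every length-k window of an encoded array (no validity check)."""
    n = arr.size - k + 1
    a = arr.astype(np.uint64)
    codes = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        codes = (codes << np.uint64(2)) | (a[j : j + n] & np.uint64(3))
    return codes


def canonical_codes(arr: np.ndarray, k: int) -> Tuple[np.ndarray, np.ndarray]:
    """Canonical 2-bit codes for every k-mer start of an encoded sequence.

    Returns (codes, valid): arrays of length len(arr)-k+1 where valid marks
    windows free of ambiguous bases.  Codes at invalid positions are
    meaningless and must be masked by the caller.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > MAX_K:
        raise ValueError(f"k must be <= {MAX_K}")
    n = arr.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    fwd = _pack_codes(arr, k)
    comp = np.where(arr < 4, 3 - arr.astype(np.int16), 4).astype(np.uint8)
    rc = _pack_codes(comp[::-1], k)[::-1]
    canon = np.minimum(fwd, rc)
    bad = np.concatenate(([0], np.cumsum(arr > 3)))
    valid = (bad[k:] - bad[:-k]) == 0
    return canon, valid


def code_to_kmer(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append("ACGT"[code & 3])
        code >>= 2
    return "".join(reversed(out))


def kmer_to_code(kmer: str) -> Optional[int]:
    arr = encode(kmer)
    if (arr > 3).any():
        return None
    code = 0
    for b in arr:
        code = (code << 2) | int(b)
    return code


@dataclass
class KmerCountTable:
    """Exact canonical k-mer counts for one read set.

    ``codes`` is a sorted uint64 array of packed canonical k-mers with
    parallel ``counts``.  ``total_count`` is the sum of all counts (the total
    number of counted k-mer windows).  After filtering against a reference,
    ``full_total_count`` preserves the pre-filter total so coverage
    normalization can still use all read k-mers.
    """

    k: int
    codes: np.ndarray
    counts: np.ndarray
    total_count: int
    full_total_count: Optional[int] = None

    @property
    def coverage_total(self) -> int:
        """Total used for coverage normalization (pre-filter when available)."""
        return self.full_total_count if self.full_total_count is not None else self.total_count

    @classmethod
    def from_dict(cls, k: int, counts: Dict[str, int]) -> "KmerCountTable":
        pairs = []
        for kmer, cnt in counts.items():
            code = kmer_to_code(kmer)
            if code is None or len(kmer) != k:
                raise ValueError(f"invalid k-mer key {kmer!r} for k={k}")
            if canonical(kmer) != kmer:
                raise ValueError(f"k-mer key {kmer!r} is not canonical")
            pairs.append((code, cnt))
        pairs.sort()
        codes = np.array([p[0] for p in pairs], dtype=np.uint64)
        cnts = np.array([p[1] for p in pairs], dtype=np.int64)
        return cls(k=k, codes=codes, counts=cnts, total_count=int(cnts.sum()))

    def get(self, kmer: str, default: int = 0) -> int:
        """Count of a k-mer, queried through its canonical form."""
        canon = canonical(kmer)
        if canon is None:
            return default
        code = kmer_to_code(canon)
        i = np.searchsorted(self.codes, np.uint64(code))
        if i < self.codes.size and self.codes[i] == np.uint64(code):
            return int(self.counts[i])
        return default

    def __contains__(self, kmer: str) -> bool:
        canon = canonical(kmer)
        if canon is None:
            return False
        code = kmer_to_code(canon)
        i = np.searchsorted(self.codes, np.uint64(code))
        return bool(i < self.codes.size and self.codes[i] == np.uint64(code))

    def __len__(self) -> int:
        return int(self.codes.size)

    def items(self) -> Iterator[Tuple[str, int]]:
        for code, cnt in zip(self.codes, self.counts):
            yield code_to_kmer(int(code), self.k), int(cnt)

    def lookup_codes(self, codes: np.ndarray) -> np.ndarray:
        """Vectorized count lookup; absent codes yield 0."""
        idx = np.searchsorted(self.codes, codes)
        idx_clip = np.minimum(idx, max(self.codes.size - 1, 0))
        if self.codes.size == 0:
            return np.zeros(codes.size, dtype=np.int64)
        hit = self.codes[idx_clip] == codes
        return np.where(hit, self.counts[idx_clip], 0)


@dataclass
class ReferenceIndex:
    """Per-position canonical k-mers of the reference genome.

    ``chroms`` maps chromosome name to (codes, valid) arrays over all k-mer
    start positions; ``n_positions`` is the total number of unambiguous k-mer
    positions N (for a single N-free chromosome, N = |G| - k + 1).
    ``mult_codes``/``mult_counts`` give the reference multiplicity of each
    distinct canonical k-mer, aggregated over all chromosomes.
    """

    k: int
    chroms: Dict[str, Tuple[np.ndarray, np.ndarray]]
    chrom_lengths: Dict[str, int]
    n_positions: int
    mult_codes: np.ndarray
    mult_counts: np.ndarray

    @property
    def N(self) -> int:
        return self.n_positions

    def multiplicity(self, kmer: str) -> int:
        code = kmer_to_code(kmer)
        if code is None:
            return 0
        i = np.searchsorted(self.mult_codes, np.uint64(code))
        if i < self.mult_codes.size and self.mult_codes[i] == np.uint64(code):
            return int(self.mult_counts[i])
        return 0


_CHUNK_BASES = 8_000_000


def count_reads(reads: Iterable[SequenceRecord], k: int) -> KmerCountTable:
    """Count canonical k-mers across a read stream.

    Every length-k window of every read contributes 1 to its canonical
    form; windows containing non-ACGT characters are skipped, and reads
    shorter than k contribute nothing.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    sep = np.array([4], dtype=np.uint8)  # sentinel so windows never span reads
    chunk: List[np.ndarray] = []
    chunk_bases = 0
    collected: List[np.ndarray] = []

    def flush() -> None:
        nonlocal chunk, chunk_bases
        if not chunk:
            return
        arr = np.concatenate(chunk)
        codes, valid = canonical_codes(arr, k)
        collected.append(codes[valid])
        chunk = []
        chunk_bases = 0

    for rec in reads:
        if len(rec.sequence) < k:
            continue
        chunk.append(encode(rec.sequence))
        chunk.append(sep)
        chunk_bases += len(rec.sequence) + 1
        if chunk_bases >= _CHUNK_BASES:
            flush()
    flush()

    if collected:
        all_codes = np.concatenate(collected)
    else:
        all_codes = np.empty(0, dtype=np.uint64)
    codes, counts = np.unique(all_codes, return_counts=True)
    return KmerCountTable(
        k=k, codes=codes, counts=counts.astype(np.int64), total_count=int(all_codes.size)
    )


def index_reference(genome: List[SequenceRecord], k: int) -> ReferenceIndex:
    """Index every canonical k-mer position of the reference genome."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if not genome:
        raise ValueError("empty reference genome")
    names = [rec.name for rec in genome]
    if len(set(names)) != len(names):
        raise ValueError("duplicate chromosome names in reference")
    chroms: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    lengths: Dict[str, int] = {}
    valid_code_chunks: List[np.ndarray] = []
    n_total = 0
    for rec in genome:
        lengths[rec.name] = len(rec.sequence)
        codes, valid = canonical_codes(encode(rec.sequence), k)
        chroms[rec.name] = (codes, valid)
        n_total += int(valid.sum())
        valid_code_chunks.append(codes[valid])
    if all(len(rec.sequence) < k for rec in genome):
        raise ValueError(f"reference too short for k={k}")
    all_codes = np.concatenate(valid_code_chunks)
    mult_codes, mult_counts = np.unique(all_codes, return_counts=True)
    return ReferenceIndex(
        k=k,
        chroms=chroms,
        chrom_lengths=lengths,
        n_positions=n_total,
        mult_codes=mult_codes,
        mult_counts=mult_counts.astype(np.int64),
    )


def restrict_to_reference(table: KmerCountTable, index: ReferenceIndex) -> KmerCountTable:
    """Drop read k-mers that never occur in the reference.

    The returned table's ``total_count`` covers retained keys only, while
    ``full_total_count`` preserves the pre-filter total of the input table so
    that coverage normalization can be computed over all read k-mers.
    """
    if table.k != index.k:
        raise ValueError(f"k mismatch: table k={table.k}, index k={index.k}")
    idx = np.searchsorted(index.mult_codes, table.codes)
    idx_clip = np.minimum(idx, max(index.mult_codes.size - 1, 0))
    keep = (
        index.mult_codes[idx_clip] == table.codes
        if index.mult_codes.size
        else np.zeros(table.codes.size, dtype=bool)
    )
    codes = table.codes[keep]
    counts = table.counts[keep]
    return KmerCountTable(
        k=table.k,
        codes=codes,
        counts=counts,
        total_count=int(counts.sum()),
        full_total_count=table.coverage_total,
    )


def save_table(table: KmerCountTable, path: str | Path) -> None:
    """Persist a count table as two-column TSV with a metadata header."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        header = f"#k={table.k}\t#total={table.total_count}"
        if table.full_total_count is not None:
            header += f"\t#full_total={table.full_total_count}"
        fh.write(header + "\n")
        for kmer, cnt in table.items():
            fh.write(f"{kmer}\t{cnt}\n")


def load_table(path: str | Path) -> KmerCountTable:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        header = fh.readline().strip()
        if not header.startswith("#k="):
            raise ValueError(f"{path}: missing count-table header")
        meta = dict(f.lstrip("#").split("=", 1) for f in header.split("\t"))
        k = int(meta["k"])
        total = int(meta["total"])
        full_total = int(meta["full_total"]) if "full_total" in meta else None
        codes: List[int] = []
        counts: List[int] = []
        for line in fh:
            kmer, cnt = line.rstrip("\n").split("\t")
            code = kmer_to_code(kmer)
            if code is None or len(kmer) != k:
                raise ValueError(f"{path}: invalid k-mer {kmer!r}")
            codes.append(code)
            counts.append(int(cnt))
    order = np.argsort(np.array(codes, dtype=np.uint64))
    codes_arr = np.array(codes, dtype=np.uint64)[order]
    counts_arr = np.array(counts, dtype=np.int64)[order]
    if int(counts_arr.sum()) != total:
        raise ValueError(f"{path}: header total does not match column sum")
    return KmerCountTable(
        k=k, codes=codes_arr, counts=counts_arr, total_count=total,
        full_total_count=full_total,
    )
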