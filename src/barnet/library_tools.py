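"""Virus-library quantification and barcode-to-library matching.

Builds barcode frequency tables from library sequencing reads (barcode + UMI
between fixed flanks, UMI-deduplicated counting) and matches observed cell
barcodes against one or more libraries with a mismatch budget.
"""

from __future__ import annotations

import gzip
from collections import Counter
from collections.abc import Iterable, Iterator, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from barnet import _seq

UNMATCHED = "unmatched"
AMBIGUOUS = "ambiguous"

BARCODE_LENGTH = 20


@dataclass
class BarcodeLibrary:
    """A sequenced virus library: unique barcodes with UMI counts and
    normalised frequencies.

    ``frequencies`` always sum to 1; when the library is built from counts,
    frequency = umi_count / total UMI count.
    """

    library_id: str
    barcodes: list[str]
    umi_counts: np.ndarray
    frequencies: np.ndarray
    has_ccs: bool = False

    def __post_init__(self) -> None:
        self.umi_counts = np.asarray(self.umi_counts, dtype=np.int64)
        self.frequencies = np.asarray(self.frequencies, dtype=np.float64)
        if len(self.barcodes) != len(set(self.barcodes)):
            raise ValueError("barcodes must be unique within a library")
        if len(self.barcodes) != len(self.frequencies):
            raise ValueError("barcodes and frequencies differ in length")
        if len(self.barcodes):
            if np.any(self.frequencies <= 0):
                raise ValueError("frequencies must be positive")
            if abs(self.frequencies.sum() - 1.0) > 1e-9:
                raise ValueError("frequencies must sum to 1")

    def __len__(self) -> int:
        return len(self.barcodes)

    @classmethod
    def from_counts(
        cls,
        counts: Mapping[str, int],
        library_id: str = "library",
        has_ccs: bool = False,
    ) -> "BarcodeLibrary":
        if not counts:
            raise ValueError("cannot build a library from an empty count table")
        barcodes = sorted(counts)
        umi = np.array([counts[b] for b in barcodes], dtype=np.int64)
        if np.any(umi < 0):
            raise ValueError("counts must be non-negative")
        total = umi.sum()
        if total == 0:
            raise ValueError("all counts are zero")
        return cls(library_id, barcodes, umi, umi / total, has_ccs=has_ccs)

    def frequency_of(self, barcode: str) -> float:
        """Frequency of a barcode, 0.0 if absent (unsequenced tail is treated
        as non-repetitive)."""
        return self._freq_lookup().get(barcode, 0.0)

    def _freq_lookup(self) -> dict[str, float]:
        cache = getattr(self, "_freq_cache", None)
        if cache is None:
            cache = dict(zip(self.barcodes, self.frequencies))
            object.__setattr__(self, "_freq_cache", cache)
        return cache

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "barcode": self.barcodes,
                "umi_count": self.umi_counts,
                "frequency": self.frequencies,
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(
        cls, path: str | Path, library_id: str | None = None, has_ccs: bool = False
    ) -> "BarcodeLibrary":
        df = pd.read_csv(path, sep="\t")
        freq = df["frequency"].to_numpy(dtype=float)
        freq = freq / freq.sum()  # tolerate rounding in the stored table
        return cls(
            library_id or Path(path).stem,
            df["barcode"].astype(str).tolist(),
            df["umi_count"].to_numpy(dtype=np.int64)
            if "umi_count" in df
            else np.zeros(len(df), dtype=np.int64),
            freq,
            has_ccs=has_ccs,
        )


@dataclass
class LibraryRead:
    """One sequencing read from a library prep."""

    read_id: str
    sequence: str
    mate_sequence: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.read_id!r} has an empty sequence")


@dataclass
class ExtractionResult:
    pairs: list[tuple[str, str]]
    rejections: Counter = field(default_factory=Counter)

    @property
    def n_accepted(self) -> int:
        return len(self.pairs)


def read_fastq(path: str | Path) -> Iterator[LibraryRead]:
    """Stream a FASTQ file (gzipped or plain) as :class:`LibraryRead`."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as handle:
        for record in SeqIO.parse(handle, "fastq"):
            yield LibraryRead(record.id, str(record.seq).upper())


def _find_flank(seq: str, flank: str, max_mismatch: int, start: int = 0) -> int | None:
    """Leftmost position >= start where ``flank`` matches within
    ``max_mismatch`` substitutions; None if absent."""
    flen = len(flank)
    for i in range(start, len(seq) - flen + 1):
        mm = 0
        for a, b in zip(seq[i : i + flen], flank):
            if a != b:
                mm += 1
                if mm > max_mismatch:
                    break
        else:
            return i
    return None


def extract_barcode_umi(
    reads: Iterable[LibraryRead],
    flank5: str,
    flank3: str,
    barcode_len: int = BARCODE_LENGTH,
    umi_len: int = 20,
    max_flank_mismatch: int = 1,
) -> ExtractionResult:
    """Extract (barcode, UMI) pairs from library reads.

    Read layout follows the RT chemistry: the UMI is the ``umi_len`` bases
    immediately 5' of ``flank5``, the barcode is the ``barcode_len`` window
    between ``flank5`` and ``flank3``::

        [adapter...][UMI][flank5][barcode][flank3][...]

    Both flanks must be located within ``max_flank_mismatch`` substitutions
    and neither the barcode nor the UMI window may contain N; otherwise the
    read is rejected and tallied by reason (``flank5_not_found``,
    ``umi_truncated``, ``flank3_not_found``, ``ambiguous_base``).
    """
    if not flank5 or not flank3:
        raise ValueError("flanks must be non-empty")
    if barcode_len <= 0 or umi_len < 0:
        raise ValueError("barcode_len must be positive and umi_len non-negative")

    result = ExtractionResult(pairs=[])
    for read in reads:
        seq = read.sequence
        p5 = _find_flank(seq, flank5, max_flank_mismatch)
        if p5 is None:
            result.rejections["flank5_not_found"] += 1
            continue
        if p5 < umi_len:
            result.rejections["umi_truncated"] += 1
            continue
        bc_start = p5 + len(flank5)
        bc_end = bc_start + barcode_len
        if bc_end + len(flank3) > len(seq):
            result.rejections["flank3_not_found"] += 1
            continue
        mm3 = sum(a != b for a, b in zip(seq[bc_end : bc_end + len(flank3)], flank3))
        if mm3 > max_flank_mismatch:
            result.rejections["flank3_not_found"] += 1
            continue
        barcode = seq[bc_start:bc_end]
        umi = seq[p5 - umi_len : p5]
        if "N" in barcode or "N" in umi:
            result.rejections["ambiguous_base"] += 1
            continue
        result.pairs.append((barcode, umi))
    return result


def _merge_umis_directional(umi_reads: Counter) -> set[str]:
    """Directional 1-mismatch UMI merging (most-read UMI absorbs neighbours
    with at most roughly half its read support)."""
    kept: list[tuple[str, int]] = []
    for umi, n in sorted(umi_reads.items(), key=lambda kv: (-kv[1], kv[0])):
        absorbed = False
        for parent, pn in kept:
            if len(parent) == len(umi) and pn >= 2 * n - 1:
                if _seq.hamming(parent, umi) <= 1:
                    absorbed = True
                    break
        if not absorbed:
            kept.append((umi, n))
    return {u for u, _ in kept}


def build_library_table(
    pairs: Iterable[tuple[str, str]],
    umi_merge_mismatch: int = 0,
    library_id: str = "library",
    has_ccs: bool = False,
) -> BarcodeLibrary:
    """UMI-deduplicated barcode counting.

    ``umi_count`` per barcode is the number of distinct UMIs observed with it
    (duplicate reads of the same barcode/UMI molecule count once). With
    ``umi_merge_mismatch=1``, UMIs within one mismatch are merged
    directionally before counting, for deeply sequenced libraries.
    """
    if umi_merge_mismatch not in (0, 1):
        raise ValueError("umi_merge_mismatch must be 0 or 1")
    per_barcode: dict[str, Counter] = {}
    n = 0
    for barcode, umi in pairs:
        per_barcode.setdefault(barcode, Counter())[umi] += 1
        n += 1
    if n == 0:
        raise ValueError("no (barcode, umi) pairs to count")
    counts: dict[str, int] = {}
    for barcode, umi_reads in per_barcode.items():
        if umi_merge_mismatch == 1:
            counts[barcode] = len(_merge_umis_directional(umi_reads))
        else:
            counts[barcode] = len(umi_reads)
    return BarcodeLibrary.from_counts(counts, library_id=library_id, has_ccs=has_ccs)


def min_hamming_profile(
    queries: Sequence[str], library: BarcodeLibrary, prefix_len: int | None = None
) -> np.ndarray:
    """Minimum Hamming distance from each query to any library barcode, with
    both sides truncated to ``prefix_len`` (default: full query length)."""
    if len(library) == 0:
        raise ValueError("library is empty")
    if not len(queries):
        return np.empty(0, dtype=np.int64)
    if prefix_len is None:
        prefix_len = min(len(q) for q in queries)
    if prefix_len > min(len(b) for b in library.barcodes):
        raise ValueError("prefix_len exceeds library barcode length")
    if any(len(q) < prefix_len for q in queries):
        raise ValueError("prefix_len exceeds a query length")
    return _seq.min_hamming_to_set(
        [q[:prefix_len] for q in queries], [b[:prefix_len] for b in library.barcodes]
    )


def match_to_libraries(
    query: str,
    libraries: Sequence[BarcodeLibrary],
    max_mismatch: int = 1,
    prefix_len: int = 15,
) -> str:
    """Assign a query barcode to a library.

    Returns the library_id iff exactly one library contains a barcode within
    ``max_mismatch`` of the query's first ``prefix_len`` bases (library
    barcodes truncated to the same prefix); :data:`AMBIGUOUS` if more than
    one library matches; :data:`UNMATCHED` otherwise.
    """
    if len(query) < prefix_len:
        raise ValueError("query shorter than prefix_len")
    hits = [
        lib.library_id
        for lib in libraries
        if min_hamming_profile([query], lib, prefix_len)[0] <= max_mismatch
    ]
    if len(hits) == 1:
        return hits[0]
    if len(hits) > 1:
        return AMBIGUOUS
    return UNMATCHED


def match_many(
    queries: Sequence[str],
    libraries: Sequence[BarcodeLibrary],
    max_mismatch: int = 1,
    prefix_len: int = 15,
) -> pd.DataFrame:
    """Vectorised batch matching; one row per query with per-library minimum
    distances and the final assignment."""
    if not len(queries):
        cols = ["query", "assignment"] + [f"dist_{lib.library_id}" for lib in libraries]
        return pd.DataFrame(columns=cols)
    dists = {
        lib.library_id: min_hamming_profile(queries, lib, prefix_len)
        for lib in libraries
    }
    dist_mat = np.stack([dists[lib.library_id] for lib in libraries], axis=1)
    n_hits = (dist_mat <= max_mismatch).sum(axis=1)
    assignment = np.where(
        n_hits == 1,
        np.array([lib.library_id for lib in libraries], dtype=object)[
            dist_mat.argmin(axis=1)
        ],
        np.where(n_hits > 1, AMBIGUOUS, UNMATCHED),
    )
    out = pd.DataFrame({"query": list(queries), "assignment": assignment})
    for lib_id, d in dists.items():
        out[f"dist_{lib_id}"] = d
    return out
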