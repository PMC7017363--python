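"""Reference sequence container with O(1) composition queries.

Sequences are stored as upper-cased ASCII byte arrays together with
prefix sums of G/C base counts and CpG-dinucleotide start counts, so the
GC fraction and CpG density of any interval cost a handful of array
lookups.  This is what makes composition-matched interval randomization
(thousands of rejection draws per DMR) affordable.
"""

from __future__ import annotations

from typing import Iterator, Mapping

import numpy as np

__all__ = ["Genome"]

_C = ord("C")
_G = ord("G")


class Genome:
    """In-memory genome with per-interval GC/CpG prefix-sum queries.

    Accepts a mapping of chromosome name to sequence (str, bytes, or a
    uint8 array of ASCII codes).  Lower-case input is upper-cased; any
    base other than A/C/G/T (e.g. N) counts toward interval length but
    never toward the GC or CpG numerators.
    """

    def __init__(self, sequences: Mapping[str, "str | bytes | np.ndarray"]):
        self._seq: dict[str, np.ndarray] = {}
        self._gc_prefix: dict[str, np.ndarray] = {}
        self._cpg_prefix: dict[str, np.ndarray] = {}
        for chrom, seq in sequences.items():
            if isinstance(seq, str):
                arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8).copy()
            elif isinstance(seq, (bytes, bytearray)):
                arr = np.frombuffer(bytes(seq).upper(), dtype=np.uint8).copy()
            else:
                arr = np.asarray(seq, dtype=np.uint8).copy()
                lower = (arr >= ord("a")) & (arr <= ord("z"))
                arr[lower] -= 32
            if arr.size == 0:
                raise ValueError(f"empty sequence for chromosome {chrom!r}")
            is_gc = (arr == _C) | (arr == _G)
            gc_prefix = np.zeros(arr.size + 1, dtype=np.int32)
            np.cumsum(is_gc, out=gc_prefix[1:], dtype=np.int32)
            # cpg_prefix[k] = number of CpG dinucleotide *starts* at positions < k
            is_cpg_start = (arr[:-1] == _C) & (arr[1:] == _G)
            cpg_prefix = np.zeros(arr.size + 1, dtype=np.int32)
            np.cumsum(is_cpg_start, out=cpg_prefix[1 : arr.size], dtype=np.int32)
            cpg_prefix[arr.size] = cpg_prefix[arr.size - 1]
            self._seq[chrom] = arr
            self._gc_prefix[chrom] = gc_prefix
            self._cpg_prefix[chrom] = cpg_prefix

    @classmethod
    def from_fasta(cls, path: str) -> "Genome":
        from pyfaidx import Fasta

        with Fasta(path, as_raw=True, sequence_always_upper=True) as fa:
            return cls({name: str(fa[name][:]) for name in fa.keys()})

    # -- introspection -------------------------------------------------

    def chroms(self) -> list[str]:
        return list(self._seq)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seq

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: int(a.size) for c, a in self._seq.items()}

    def sequence(self, chrom: str, start: int, end: int) -> str:
        self._check(chrom, start, end)
        return self._seq[chrom][start:end].tobytes().decode("ascii")

    def iter_sequences(self) -> Iterator[tuple[str, str]]:
        for chrom, arr in self._seq.items():
            yield chrom, arr.tobytes().decode("ascii")

    # -- composition queries -------------------------------------------

    def _check(self, chrom: str, start: int, end: int) -> None:
        if chrom not in self._seq:
            raise KeyError(f"chromosome {chrom!r} missing from genome")
        if start < 0 or end > self._seq[chrom].size or end <= start:
            raise ValueError(f"interval {chrom}:{start}-{end} out of bounds")

    def gc_cpg(self, chrom: str, start: int, end: int) -> tuple[float, float]:
        """(GC fraction, CpG starts per bp) of ``[start, end)``.

        A CpG dinucleotide counts when both its bases lie inside the
        interval; density is the count divided by the interval length.
        """
        self._check(chrom, start, end)
        length = end - start
        gc = int(self._gc_prefix[chrom][end] - self._gc_prefix[chrom][start])
        cpg = int(self._cpg_prefix[chrom][end - 1] - self._cpg_prefix[chrom][start])
        return gc / length, cpg / length

    def gc_cpg_batch(
        self, chrom: str, starts: np.ndarray, ends: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized :meth:`gc_cpg` for equal treatment of many intervals."""
        if chrom not in self._seq:
            raise KeyError(f"chromosome {chrom!r} missing from genome")
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        lengths = (ends - starts).astype(float)
        gp, cp = self._gc_prefix[chrom], self._cpg_prefix[chrom]
        gc = (gp[ends] - gp[starts]) / lengths
        cpg = (cp[ends - 1] - cp[starts]) / lengths
        return gc, cpg

    def global_gc_cpg(self) -> tuple[float, float]:
        """Genome-wide GC fraction and CpG rate (per bp)."""
        total = sum(a.size for a in self._seq.values())
        gc = sum(int(p[-1]) for p in self._gc_prefix.values())
        cpg = sum(int(p[-1]) for p in self._cpg_prefix.values())
        return gc / total, cpg / total
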