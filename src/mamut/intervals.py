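"""Per-chromosome interval sets (0-based half-open) for callable masks.

Backed by sorted ``(k, 2)`` numpy arrays; supports the handful of operations
the pipeline needs: merge, intersect, membership and base counting.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np

__all__ = ["GenomeMask", "merge_intervals"]


def merge_intervals(arr: np.ndarray) -> np.ndarray:
    """Sort and merge overlapping or touching intervals."""
    arr = np.asarray(arr, dtype=np.int64).reshape(-1, 2)
    if arr.size == 0:
        return arr
    arr = arr[np.argsort(arr[:, 0], kind="stable")]
    out = []
    cs, ce = arr[0]
    for s, e in arr[1:]:
        if s <= ce:
            ce = max(ce, e)
        else:
            out.append((cs, ce))
            cs, ce = s, e
    out.append((cs, ce))
    return np.asarray(out, dtype=np.int64)


class GenomeMask:
    """An immutable set of genomic intervals, merged per chromosome."""

    def __init__(self, intervals: Mapping[str, Iterable]):
        self._ivs: dict[str, np.ndarray] = {}
        for chrom, arr in intervals.items():
            a = np.asarray(list(arr) if not isinstance(arr, np.ndarray) else arr)
            a = a.reshape(-1, 2).astype(np.int64)
            if a.size and np.any(a[:, 1] <= a[:, 0]):
                bad = a[a[:, 1] <= a[:, 0]][0]
                raise ValueError(
                    f"{chrom}: interval end <= start ({bad[0]}, {bad[1]})"
                )
            merged = merge_intervals(a)
            if merged.size:
                self._ivs[chrom] = merged

    # -- introspection -----------------------------------------------------
    @property
    def chromosomes(self) -> tuple[str, ...]:
        return tuple(self._ivs)

    def intervals(self, chrom: str) -> np.ndarray:
        return self._ivs.get(chrom, np.empty((0, 2), dtype=np.int64))

    def total_bases(self) -> int:
        return int(
            sum((a[:, 1] - a[:, 0]).sum() for a in self._ivs.values())
        )

    def __bool__(self) -> bool:
        return bool(self._ivs)

    # -- queries -----------------------------------------------------------
    def contains(self, chrom: str, positions) -> np.ndarray:
        """Vectorized membership of 0-based positions."""
        pos = np.atleast_1d(np.asarray(positions, dtype=np.int64))
        iv = self.intervals(chrom)
        if iv.size == 0:
            return np.zeros(pos.shape, dtype=bool)
        idx = np.searchsorted(iv[:, 0], pos, side="right") - 1
        ok = idx >= 0
        ok[ok] &= pos[ok] < iv[idx[ok], 1]
        return ok

    def intersect(self, other: "GenomeMask") -> "GenomeMask":
        out: dict[str, list[tuple[int, int]]] = {}
        for chrom in self._ivs:
            a, b = self.intervals(chrom), other.intervals(chrom)
            if a.size == 0 or b.size == 0:
                continue
            res, i, j = [], 0, 0
            while i < len(a) and j < len(b):
                s = max(a[i, 0], b[j, 0])
                e = min(a[i, 1], b[j, 1])
                if s < e:
                    res.append((s, e))
                if a[i, 1] < b[j, 1]:
                    i += 1
                else:
                    j += 1
            if res:
                out[chrom] = res
        return GenomeMask(out)

    def shifted(self, offset: int) -> "GenomeMask":
        return GenomeMask(
            {c: a + offset for c, a in self._ivs.items()}
        )

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def from_bed(
        cls, path, chrom_lengths: Mapping[str, int] | None = None
    ) -> "GenomeMask":
        ivs: dict[str, list[tuple[int, int]]] = {}
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValueError(f"{path}:{ln}: fewer than 3 BED columns")
                chrom, s, e = parts[0], int(parts[1]), int(parts[2])
                if e <= s:
                    raise ValueError(f"{path}:{ln}: end <= start")
                if chrom_lengths is not None:
                    if chrom not in chrom_lengths:
                        raise ValueError(f"{path}:{ln}: unknown chromosome {chrom}")
                    if e > chrom_lengths[chrom]:
                        raise ValueError(
                            f"{path}:{ln}: interval exceeds {chrom} length"
                        )
                ivs.setdefault(chrom, []).append((s, e))
        return cls(ivs)

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self._ivs):
                for s, e in self._ivs[chrom]:
                    fh.write(f"{chrom}\t{s}\t{e}\n")
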