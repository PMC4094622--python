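"""Exhaustive mismatch-tolerant short-read matching.

This is the pipeline's internal stand-in for an external aligner: it reports
*every* position on both strands of a reference set where a query matches
with at most ``max_mismatch`` substitutions, optionally restricted to the
best stratum (fewest mismatches).  Exhaustiveness is guaranteed by pigeonhole
seeding: a query split into ``max_mismatch + 1`` contiguous chunks must match
one chunk exactly, so seeding on each chunk's leading k-mer enumerates every
candidate position; each candidate is then verified by direct comparison.
Queries too short to seed fall back to a full sliding-window scan.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import revcomp

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


def encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class Hit:
    """One reported match of a query against a reference sequence."""

    ref: str
    start: int  # 0-based, on the reference forward strand
    strand: str  # '+' if the query matches forward, '-' if its revcomp does
    mismatches: int


class MismatchIndex:
    """Seed index over a set of reference sequences.

    Parameters
    ----------
    references : dict[str, str]
        Reference name -> sequence.
    k : int
        Seed length.  Queries shorter than ``(max_mismatch + 1) * k`` are
        handled by brute-force scan instead of seeding.
    """

    def __init__(self, references: dict[str, str], k: int = 12):
        self.k = k
        self.names = list(references)
        # concatenate with a sentinel (code 4) between sequences so no k-mer
        # or verification window spans two references
        parts, offsets = [], []
        pos = 0
        for name in self.names:
            arr = encode(references[name])
            offsets.append((pos, pos + len(arr)))
            parts.append(arr)
            parts.append(np.full(1, 4, dtype=np.uint8))
            pos += len(arr) + 1
        self.big = np.concatenate(parts) if parts else np.zeros(0, np.uint8)
        self.offsets = offsets
        self._ref_of_pos = np.zeros(len(self.big), dtype=np.int32)
        for i, (s, e) in enumerate(offsets):
            self._ref_of_pos[s:e] = i
        self._build_seed_index()

    def _build_seed_index(self) -> None:
        k, big = self.k, self.big
        n = len(big) - k + 1
        if n <= 0:
            self._codes_sorted = np.zeros(0, dtype=np.int64)
            self._pos_sorted = np.zeros(0, dtype=np.int64)
            return
        codes = np.zeros(n, dtype=np.int64)
        valid = np.ones(n, dtype=bool)
        for j in range(k):
            window = big[j : j + n]
            codes = codes * 4 + np.minimum(window, 3)
            valid &= window < 4
        pos = np.nonzero(valid)[0]
        codes = codes[pos]
        order = np.argsort(codes, kind="stable")
        self._codes_sorted = codes[order]
        self._pos_sorted = pos[order]

    def _seed_positions(self, code: int) -> np.ndarray:
        lo = np.searchsorted(self._codes_sorted, code, side="left")
        hi = np.searchsorted(self._codes_sorted, code, side="right")
        return self._pos_sorted[lo:hi]

    def _verify(self, qarr: np.ndarray, starts: np.ndarray, max_mm: int):
        """Mismatch-count verification of candidate global start positions."""
        L = len(qarr)
        ok = (starts >= 0) & (starts + L <= len(self.big))
        starts = np.unique(starts[ok])
        if len(starts) == 0:
            return starts, starts
        windows = self.big[starts[:, None] + np.arange(L)[None, :]]
        mm = np.count_nonzero(windows != qarr[None, :], axis=1)
        keep = mm <= max_mm
        return starts[keep], mm[keep]

    def _candidates(self, qarr: np.ndarray, max_mm: int) -> np.ndarray:
        L, k = len(qarr), self.k
        n_chunks = max_mm + 1
        if L < n_chunks * k:
            # brute force: every start position is a candidate
            return np.arange(len(self.big) - L + 1, dtype=np.int64)
        bounds = np.linspace(0, L, n_chunks + 1).astype(int)
        cands = []
        for c in range(n_chunks):
            off = bounds[c]
            seed = qarr[off : off + k]
            if np.any(seed >= 4):
                continue
            code = 0
            for b in seed:
                code = code * 4 + int(b)
            cands.append(self._seed_positions(code) - off)
        if not cands:
            return np.zeros(0, dtype=np.int64)
        return np.concatenate(cands)

    def find(
        self, seq: str, max_mismatch: int, best_stratum: bool = True
    ) -> list[Hit]:
        """All matches of *seq* (both strands) with <= max_mismatch.

        With ``best_stratum`` (the default), hits with more mismatches than
        the best hit anywhere (either strand) are suppressed, mirroring
        ``--best --strata`` semantics.
        """
        if not seq or len(self.big) == 0:
            return []
        hits: list[Hit] = []
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            qarr = encode(s)
            if len(qarr) > len(self.big):
                continue
            starts = self._candidates(qarr, max_mismatch)
            starts, mm = self._verify(qarr, starts, max_mismatch)
            for g, m in zip(starts, mm):
                ref_i = int(self._ref_of_pos[g])
                ref_s, ref_e = self.offsets[ref_i]
                if g + len(qarr) > ref_e:
                    continue  # window ran into the sentinel/next reference
                hits.append(
                    Hit(self.names[ref_i], int(g - ref_s), strand, int(m))
                )
        if best_stratum and hits:
            best = min(h.mismatches for h in hits)
            hits = [h for h in hits if h.mismatches == best]
        hits.sort(key=lambda h: (h.ref, h.start, h.strand))
        return hits
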