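"""Exact k-mer anchored micro-aligner for desk-scale detection work.

Anchors are exact k-mer matches grouped by diagonal (substitution-only
alignment, no gaps); each diagonal cluster is scored by direct base
comparison and extended outwards with an X-drop rule.  Real BLASTN or
minimap2 output can always be substituted through the io_formats readers;
this aligner exists so the detectors are testable without external
binaries, and it shares the substitution-only assumption of the synthetic
genome generator.
"""

from __future__ import annotations

from .io_formats import AlignmentHit

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


class KmerAligner:
    """Index a target sequence once; align many queries against it."""

    def __init__(self, target: str, target_name: str = "target", k: int = 16):
        self.target = target.upper()
        self.target_name = target_name
        self.k = k
        self.index: dict[str, list[int]] = {}
        for i in range(len(self.target) - k + 1):
            kmer = self.target[i : i + k]
            if "N" in kmer:
                continue
            self.index.setdefault(kmer, []).append(i)

    # -- internals ---------------------------------------------------------

    def _anchors(self, query: str) -> dict[int, list[int]]:
        """Exact k-mer matches grouped by diagonal (tpos - qpos)."""
        k = self.k
        diags: dict[int, list[int]] = {}
        for q in range(len(query) - k + 1):
            hits = self.index.get(query[q : q + k])
            if hits:
                for t in hits:
                    diags.setdefault(t - q, []).append(q)
        return diags

    def _xdrop_extend(self, query: str, diag: int, qs: int, qe: int,
                      match: int = 1, mismatch: int = -3, xdrop: int = 20):
        """Extend [qs, qe) on one diagonal in both directions."""
        t = self.target
        # right
        best, score, best_qe = 0, 0, qe
        q = qe
        while q < len(query) and q + diag < len(t):
            score += match if query[q] == t[q + diag] else mismatch
            q += 1
            if score > best:
                best, best_qe = score, q
            elif best - score > xdrop:
                break
        # left
        best, score, best_qs = 0, 0, qs
        q = qs - 1
        while q >= 0 and q + diag >= 0:
            score += match if query[q] == t[q + diag] else mismatch
            if score > best:
                best, best_qs = score, q
            elif best - score > xdrop:
                break
            q -= 1
        return best_qs, best_qe

    def _align_one_strand(self, query: str, query_name: str, strand: str,
                          min_len: int, min_identity: float,
                          max_anchor_gap: int) -> list[AlignmentHit]:
        k = self.k
        hits = []
        qlen = len(query)
        for diag, qpos in self._anchors(query).items():
            qpos.sort()
            # split anchor runs at large gaps
            clusters: list[tuple[int, int]] = []
            start = prev = qpos[0]
            for q in qpos[1:]:
                if q - prev > max_anchor_gap:
                    clusters.append((start, prev + k))
                    start = q
                prev = q
            clusters.append((start, prev + k))
            for qs, qe in clusters:
                qs, qe = self._xdrop_extend(query, diag, qs, qe)
                if qe - qs < min_len:
                    continue
                tseg = self.target[qs + diag : qe + diag]
                matches = sum(a == b for a, b in zip(query[qs:qe], tseg))
                block_len = qe - qs
                if matches / block_len < min_identity:
                    continue
                if strand == "+":
                    q0, q1 = qs, qe
                else:  # query was reverse-complemented before anchoring
                    q0, q1 = qlen - qe, qlen - qs
                hits.append(
                    AlignmentHit(
                        query_name=query_name, query_start=q0, query_end=q1,
                        target_name=self.target_name,
                        target_start=qs + diag, target_end=qe + diag,
                        strand=strand, matches=matches, block_len=block_len,
                    )
                )
        return hits

    # -- public ------------------------------------------------------------

    def align(self, query: str, query_name: str = "query", min_len: int = 300,
              min_identity: float = 0.8, max_anchor_gap: int = 500,
              both_strands: bool = True) -> list[AlignmentHit]:
        """All gapless local alignments of ``query`` against the target."""
        query = query.upper()
        hits = self._align_one_strand(query, query_name, "+", min_len,
                                      min_identity, max_anchor_gap)
        if both_strands:
            hits += self._align_one_strand(revcomp(query), query_name, "-",
                                           min_len, min_identity, max_anchor_gap)
        hits.sort(key=lambda h: (h.target_start, h.target_end, h.strand))
        return hits


def self_hits(seq: str, name: str = "self", min_len: int = 300,
              min_identity: float = 0.8, k: int = 16) -> list[AlignmentHit]:
    """Self-alignment of a region, with the trivial full-length diagonal
    removed (plus-strand hits where query and target intervals coincide)."""
    aligner = KmerAligner(seq, target_name=name, k=k)
    hits = aligner.align(seq, query_name=name, min_len=min_len,
                         min_identity=min_identity)
    return [
        h for h in hits
        if not (h.strand == "+" and h.query_start == h.target_start
                and h.query_end == h.target_end)
    ]
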