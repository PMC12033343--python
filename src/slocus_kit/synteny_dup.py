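"""Synteny-block and segmental-duplication detection.

Anchor-and-chain strategy on exact k-mer matches (both strands): anchors on
a shared (anti-)diagonal are merged into runs, runs are chained when
colinear within a gap limit, chain ends are extended by X-drop, and the
chained span's identity is computed from the anchors plus alignment of the
inter-anchor gaps.  Blocks below a minimum length or identity are
discarded; the defaults (300 bp, 78%) are the connector-line filters used
for locus-scale dot plots, and the duplication search (self-vs-self, with
the trivial diagonal removed) targets the multi-kb near-identical blocks
that border-repeat families flank.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .alignment import nucleotide_global_aligner, nucleotide_local_aligner
from .codons import revcomp
from .io_formats import Interval, SeqRecord


@dataclass
class SyntenyBlock:
    seq_a: str
    seq_b: str
    interval_a: Interval
    interval_b: Interval
    strand: str  # "same" | "inverted"
    length: int
    identity_pct: float


@dataclass
class DuplicationBlock:
    seq_id: str
    interval_a: Interval
    interval_b: Interval
    length: int
    identity_pct: float
    border_repeat_match: bool


# ---------------------------------------------------------------------------
# anchors and chains


def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    idx: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        idx.setdefault(seq[i : i + k], []).append(i)
    return idx


def _anchors(seq_a: str, seq_b: str, k: int, *, self_mode: bool) -> list[tuple[int, int, str]]:
    """(a_pos, b_pos, strand) exact k-mer matches; '-' anchors use forward
    coordinates of B's leftmost base of the matching window."""
    idx = _kmer_index(seq_a, k)
    out: list[tuple[int, int, str]] = []
    for j in range(len(seq_b) - k + 1):
        kmer = seq_b[j : j + k]
        for i in idx.get(kmer, ()):
            if self_mode and i >= j:
                continue  # trivial diagonal and mirror images
            out.append((i, j, "+"))
    rc = revcomp(seq_b)
    Lb = len(seq_b)
    for j in range(len(rc) - k + 1):
        kmer = rc[j : j + k]
        for i in idx.get(kmer, ()):
            fwd = Lb - j - k  # leftmost base on forward strand of B
            if self_mode and i >= fwd:
                continue
            out.append((i, fwd, "-"))
    return out


@dataclass
class _Chain:
    a0: int
    a1: int  # half-open span in A
    b0: int
    b1: int
    strand: str
    anchors: list[tuple[int, int]]


def _chain_anchors(
    anchors: list[tuple[int, int, str]], k: int, max_gap: int, A: str, B: str, min_id: float
) -> list[_Chain]:
    chains: list[_Chain] = []
    for strand in ("+", "-"):
        sub = [(a, b) for a, b, s in anchors if s == strand]
        if not sub:
            continue
        # group into exact-diagonal runs first
        diag = (lambda a, b: a - b) if strand == "+" else (lambda a, b: a + b)
        sub.sort(key=lambda ab: (diag(*ab), ab[0]))
        runs: list[_Chain] = []
        for a, b in sub:
            r = runs[-1] if runs else None
            if (
                r is not None
                and diag(a, b) == diag(r.anchors[-1][0], r.anchors[-1][1])
                and 0 < a - r.anchors[-1][0] <= max_gap
            ):
                r.anchors.append((a, b))
                r.a1 = a + k
                r.b0, r.b1 = min(r.b0, b), max(r.b1, b + k)
            else:
                runs.append(_Chain(a, a + k, b, b + k, strand, [(a, b)]))
        # chain colinear runs
        runs.sort(key=lambda r: (r.a0, r.b0))
        merged: list[_Chain] = []
        for r in runs:
            placed = False
            for c in merged:
                if r.a0 < c.a1 - k or r.a0 - c.a1 > max_gap:
                    continue
                if strand == "+":
                    ok = 0 <= r.b0 - c.anchors[-1][1] <= max_gap + k and r.b0 >= c.b1 - k
                else:
                    ok = 0 <= c.anchors[-1][1] - r.b1 <= max_gap + k and r.b1 <= c.b0 + k
                if ok:
                    # only bridge gaps that themselves look homologous;
                    # otherwise unrelated colinear segments would be fused
                    prev, cur = c.anchors[-1], r.anchors[0]
                    frac, cols = _gap_identity(A, B, strand, prev, cur, k)
                    if cols >= 30 and frac * 100.0 < min_id:
                        continue
                    c.anchors.extend(r.anchors)
                    c.a1 = max(c.a1, r.a1)
                    c.b0, c.b1 = min(c.b0, r.b0), max(c.b1, r.b1)
                    placed = True
                    break
            if not placed:
                merged.append(r)
        chains.extend(merged)
    return chains


def _gap_identity(seq_a: str, seq_b: str, chain_strand: str, prev: tuple[int, int], cur: tuple[int, int], k: int) -> tuple[float, int]:
    """Identity of the inter-anchor gap between two anchors (fraction, gap columns)."""
    (pa, pb), (a, b) = prev, cur
    ga = seq_a[pa + k : a]
    if chain_strand == "+":
        gb = seq_b[pb + k : b]
    else:
        gb = revcomp(seq_b[b + k : pb])
    n = max(len(ga), len(gb))
    if n == 0:
        return 1.0, 0
    if not ga or not gb:
        return 0.0, n
    from .alignment import nucleotide_global_aligner

    aln = nucleotide_global_aligner().align(ga, gb)[0]
    match = sum(
        1
        for (x0, x1), (y0, y1) in zip(*aln.aligned)
        for t in range(x1 - x0)
        if ga[x0 + t] == gb[y0 + t]
    )
    cols = len(ga) + len(gb) - sum((x1 - x0) for x0, x1 in aln.aligned[0])
    return match / cols, cols


def _trim_chain_ends(chain: _Chain, A: str, B: str, k: int, min_id: float) -> None:
    """Drop terminal anchors whose connecting gap is long and clearly below
    the identity filter — these are chance k-mer matches in diverged flanks
    (e.g. border repeats) sitting on the block's diagonal."""
    reverse_b = chain.strand == "-"
    anchors = sorted(set(chain.anchors), key=lambda ab: (ab[0], -ab[1] if reverse_b else ab[1]))
    # group anchors into clusters separated by >40 bp along A; inside a
    # block passing the identity filter anchors are dense, so a small
    # terminal cluster across a sub-threshold gap is a chance match in a
    # diverged flank (e.g. a border repeat) on the block's diagonal
    clusters: list[list[tuple[int, int]]] = [[anchors[0]]]
    for ab in anchors[1:]:
        if ab[0] - clusters[-1][-1][0] > 40:
            clusters.append([ab])
        else:
            clusters[-1].append(ab)
    changed = True
    while changed and len(clusters) >= 2:
        changed = False
        for side in (0, -1):
            if len(clusters) < 2:
                break
            outer = clusters[side]
            inner = clusters[1] if side == 0 else clusters[-2]
            span = outer[-1][0] + k - outer[0][0]
            prev, cur = (outer[-1], inner[0]) if side == 0 else (inner[-1], outer[0])
            frac, cols = _gap_identity(A, B, chain.strand, prev, cur, k)
            if span <= 150 and cols >= 30 and frac * 100.0 < min_id:
                clusters.pop(side)
                changed = True
    anchors = [ab for cl in clusters for ab in cl]
    chain.anchors = anchors
    chain.a0 = anchors[0][0]
    chain.a1 = max(a for a, _ in anchors) + k
    chain.b0 = min(b for _, b in anchors)
    chain.b1 = max(b for _, b in anchors) + k


def _xdrop_extend(seq_a: str, seq_b: str, i: int, j: int, di: int, dj: int, drop: int = 10) -> int:
    """Ungapped extension from (i, j) in direction (di, dj); returns the
    number of columns giving the best running score."""
    score = best = 0
    best_steps = steps = 0
    while 0 <= i < len(seq_a) and 0 <= j < len(seq_b):
        score += 1 if seq_a[i] == seq_b[j] else -4
        steps += 1
        if score > best:
            best, best_steps = score, steps
        if best - score > drop:
            break
        i += di
        j += dj
    return best_steps


def _span_identity(seq_a: str, seq_b_oriented: str, chain: _Chain, k: int) -> tuple[float, int]:
    """Identity over the chained span: anchors count as exact matches,
    inter-anchor gaps are globally aligned."""
    anchors = sorted(set(chain.anchors))
    if chain.strand == "-":
        # map anchors into coordinates of the reverse-complemented B window
        anchors = sorted((a, chain.b1 - k - b) for a, b in anchors)
    ident = cols = 0
    aligner = nucleotide_global_aligner()
    pa, pb = None, None
    for a, b in anchors:
        if pa is None:
            pa, pb = a, b
            ident += k
            cols += k
            continue
        if a < pa + k or b < pb + k:
            # overlapping anchor: count only the new columns as matches
            adv = max(a + k - (pa + k), 0)
            ident += adv
            cols += adv
            pa, pb = a, b
            continue
        pa_gap = seq_a[pa + k : a]
        pb_gap = _bslice(seq_b_oriented, chain, pb + k, b, k)
        if pa_gap or pb_gap:
            if not pa_gap or not pb_gap:
                cols += max(len(pa_gap), len(pb_gap))
            else:
                aln = aligner.align(pa_gap, pb_gap)[0]
                n_match = sum(
                    1
                    for (x0, x1), (y0, y1) in zip(*aln.aligned)
                    for t in range(x1 - x0)
                    if pa_gap[x0 + t] == pb_gap[y0 + t]
                )
                n_cols = len(pa_gap) + len(pb_gap) - sum(
                    (x1 - x0) for x0, x1 in aln.aligned[0]
                )
                ident += n_match
                cols += n_cols
        ident += k
        cols += k
        pa, pb = a, b
    if cols == 0:
        return 0.0, 0
    return 100.0 * ident / cols, cols


def _bslice(seq_b_oriented: str, chain: _Chain, b_from: int, b_to: int, k: int) -> str:
    if chain.strand == "+":
        return seq_b_oriented[b_from:b_to]
    # oriented string is revcomp of B's chain window; coordinates already mapped
    return seq_b_oriented[b_from:b_to]


def find_synteny(
    a: SeqRecord,
    b: SeqRecord,
    k: int = 15,
    max_gap: int = 1000,
    min_len: int = 300,
    min_id: float = 78.0,
    *,
    _self_mode: bool = False,
) -> list[SyntenyBlock]:
    """Syntenic blocks between two sequences on both strands.

    Blocks shorter than ``min_len`` or below ``min_id`` percent identity
    over the chained span are discarded.
    """
    if k < 11:
        raise ValueError("k must be >= 11")
    if not a.seq or not b.seq:
        raise ValueError("empty sequence")
    A, B = a.seq.upper(), b.seq.upper()
    if k > len(A) or k > len(B):
        warnings.warn("k longer than a sequence; no anchors possible")
        return []
    anchors = _anchors(A, B, k, self_mode=_self_mode)
    chains = _chain_anchors(anchors, k, max_gap, A, B, min_id)
    blocks: list[SyntenyBlock] = []
    for c in chains:
        _trim_chain_ends(c, A, B, k, min_id)
        # X-drop extension of both ends
        if c.strand == "+":
            left = _xdrop_extend(A, B, c.a0 - 1, c.b0 - 1, -1, -1)
            right = _xdrop_extend(A, B, c.a1, c.b1, 1, 1)
            c.a0 -= left
            c.b0 -= left
            c.a1 += right
            c.b1 += right
        else:
            left = _xdrop_extend(A, B, c.a0 - 1, c.b1, -1, 1)
            right = _xdrop_extend(A, B, c.a1, c.b0 - 1, 1, -1)
            c.a0 -= left
            c.b1 += left
            c.a1 += right
            c.b0 -= right
        c.anchors = [(x, y) for x, y in c.anchors]
        span_len = max(c.a1 - c.a0, c.b1 - c.b0)
        if span_len < min_len:
            continue
        oriented = B if c.strand == "+" else revcomp(B[c.b0 : c.b1])
        if c.strand == "-":
            # remap anchors into the oriented window inside _span_identity
            pass
        ident, _cols = _span_identity(A, oriented, c, k)
        # account for extended flanks in identity (ungapped, count matches)
        ident = _extended_identity(A, B, c, k, ident)
        if ident < min_id:
            continue
        blocks.append(
            SyntenyBlock(
                seq_a=a.id,
                seq_b=b.id,
                interval_a=Interval(c.a0, c.a1),
                interval_b=Interval(c.b0, c.b1),
                strand="same" if c.strand == "+" else "inverted",
                length=span_len,
                identity_pct=round(ident, 2),
            )
        )
    blocks.sort(key=lambda bl: (bl.interval_a.start, bl.interval_b.start))
    return blocks


def _extended_identity(A: str, B: str, c: _Chain, k: int, core_ident: float) -> float:
    """Blend the anchor-span identity with exact comparison over the
    X-drop-extended flanks (ungapped by construction)."""
    anchors = sorted(set(c.anchors))
    if c.strand == "+":
        core_a0, core_a1 = anchors[0][0], anchors[-1][0] + k
    else:
        core_a0, core_a1 = anchors[0][0], max(x for x, _ in anchors) + k
    core_cols = core_a1 - core_a0
    total_cols = core_cols
    total_ident = core_ident / 100.0 * core_cols
    for lo, hi in ((c.a0, core_a0), (core_a1, c.a1)):
        n = hi - lo
        if n <= 0:
            continue
        if c.strand == "+":
            off = c.b0 - c.a0
            bseg = B[lo + off : hi + off]
        else:
            anti = c.a0 + c.b1  # a + b_end constant on an anti-diagonal
            bseg = revcomp(B[anti - hi : anti - lo])
        aseg = A[lo:hi]
        m = sum(1 for x, y in zip(aseg, bseg) if x == y)
        total_ident += m
        total_cols += max(len(aseg), len(bseg))
    return 100.0 * total_ident / total_cols if total_cols else 0.0


# ---------------------------------------------------------------------------
# segmental duplications


def _border_match(seq: str, iv: Interval, repeats: list[SeqRecord], window: int, min_frac: float) -> bool:
    aligner = nucleotide_local_aligner()
    flanks = [
        seq[max(0, iv.start - window) : iv.start],
        seq[iv.end : iv.end + window],
    ]
    for rep in repeats:
        for fl in flanks:
            if len(fl) < 20:
                continue
            if aligner.score(fl, rep.seq.upper()) >= min_frac * len(rep.seq):
                return True
    return False


def find_segmental_duplications(
    record: SeqRecord,
    k: int = 15,
    max_gap: int = 1000,
    min_len: int = 5000,
    min_id: float = 90.0,
    border_repeats: list[SeqRecord] | None = None,
    border_window: int = 1000,
    border_min_frac: float = 0.4,
) -> list[DuplicationBlock]:
    """Within-sequence duplications: self-vs-self synteny with the trivial
    diagonal removed and mirrored hits merged at the anchor level."""
    blocks = find_synteny(
        record, record, k=k, max_gap=max_gap, min_len=min_len, min_id=min_id, _self_mode=True
    )
    out: list[DuplicationBlock] = []
    for b in blocks:
        ia, ib = sorted([b.interval_a, b.interval_b])
        if ia.overlap(ib) > 0:
            continue
        matched = False
        if border_repeats:
            matched = _border_match(
                record.seq.upper(), ia, border_repeats, border_window, border_min_frac
            ) and _border_match(
                record.seq.upper(), ib, border_repeats, border_window, border_min_frac
            )
        out.append(
            DuplicationBlock(
                seq_id=record.id,
                interval_a=ia,
                interval_b=ib,
                length=b.length,
                identity_pct=b.identity_pct,
                border_repeat_match=matched,
            )
        )
    out.sort(key=lambda d: (d.interval_a.start, d.interval_b.start))
    return out
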