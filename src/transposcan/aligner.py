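"""Seed-and-extend local nucleotide alignment (blastn-like).

The engine indexes exact words of ``word_size`` (default 7), extends each
seed ungapped under an x-drop rule, then chains compatible HSPs across small
gaps with affine penalties.  E-values follow the ungapped Karlin-Altschul
form E = K*m*n*exp(-lambda*S).  Both orientations are searched by
reverse-complementing the subject; coordinates are always reported on the
forward strand.  A DUST-style triplet-frequency filter removes
low-complexity ("simple sequence") hits.

This is the single alignment engine used by every pipeline stage; searches
against the same subject reuse a :class:`SubjectIndex`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from functools import cached_property

import numpy as np
from numba import njit

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_RC_TABLE = str.maketrans("ACGTNacgtn", "TGCANtgcan")


@dataclass(frozen=True)
class AlignmentConfig:
    """Scoring and filtering parameters for the local aligner.

    The defaults (word size 7, E-value cutoff 0.1, +1/-3 match/mismatch with
    the corresponding ungapped Karlin-Altschul parameters) are the profile
    used for the ingroup-vs-ingroup searches.  ``relaxed()`` returns a
    profile for deep-divergence outgroup searches.
    """

    word_size: int = 7
    evalue_cutoff: float = 0.1
    match: int = 1
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2
    karlin_lambda: float = 1.374
    karlin_k: float = 0.711
    x_drop: int = 20
    max_n_run: int = 10
    max_chain_gap: int = 50
    dust_threshold: float = 2.0
    dust_window: int = 64
    filter_low_complexity: bool = True

    def __post_init__(self):
        if self.word_size < 4:
            raise ValueError("word_size must be >= 4")
        if not (self.match > 0 > self.mismatch):
            raise ValueError("need match > 0 > mismatch")
        if self.karlin_lambda <= 0 or self.karlin_k <= 0:
            raise ValueError("Karlin-Altschul parameters must be positive")

    def relaxed(self) -> "AlignmentConfig":
        """Profile for searches across deep divergence (~60-65% identity).

        +1/-1 scoring keeps the expected per-column score positive down to
        50% identity; lambda = ln 3 is the exact ungapped solution for that
        score system at uniform base composition, K is approximate.
        """
        return replace(self, match=1, mismatch=-1, evalue_cutoff=1.0,
                       karlin_lambda=math.log(3.0), karlin_k=0.333, x_drop=25)


@dataclass
class HSP:
    """One local alignment hit, coordinates 0-based half-open, forward strand."""

    q_id: str
    s_id: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    orientation: str  # "forward" | "reverse"
    length: int       # aligned columns including gap columns
    identity: float
    score: int
    evalue: float

    @property
    def identities(self) -> int:
        return round(self.identity * self.length)


def reverse_complement(seq: str) -> str:
    """Standard reverse complement; N maps to N; involution."""
    bad = set(seq) - set("ACGTNacgtn")
    if bad:
        raise ValueError(f"cannot reverse-complement characters {sorted(bad)}")
    return seq.translate(_RC_TABLE)[::-1]


def encode(seq: str) -> np.ndarray:
    """A/C/G/T -> 0..3, anything else -> 4 (treated as N)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def evalue(score: float, m: int, n: int, config: AlignmentConfig) -> float:
    """Karlin-Altschul expectation for a score over search space m*n."""
    return config.karlin_k * m * n * math.exp(-config.karlin_lambda * score)


def min_repeat_score(config: AlignmentConfig, m: int, n: int) -> int:
    """Smallest integer score at least as significant as a 15/15 exact match.

    The flanking-repeat threshold is phrased as an e-value floor ("hits
    greater than or equal to the e-value of a 15/15 bp exact match"), so a
    gapped or imperfect repeat longer than 15 bp can qualify.  Under pure
    match-count scoring this is exactly 15*match.
    """
    target = evalue(15 * config.match, m, n, config)
    s = 0
    while evalue(s, m, n, config) > target:
        s += 1
    return s


# ---------------------------------------------------------------------------
# low-complexity (DUST-style) filtering
# ---------------------------------------------------------------------------


def _triplet_codes(a: np.ndarray) -> np.ndarray:
    """Triplet codes 0..63, or 64 where the window touches an N."""
    L = len(a) - 2
    if L <= 0:
        return np.empty(0, dtype=np.int64)
    t = a[:L].astype(np.int64) * 16 + a[1 : L + 1] * 4 + a[2 : L + 2]
    invalid = (a[:L] > 3) | (a[1 : L + 1] > 3) | (a[2 : L + 2] > 3)
    t[invalid] = 64
    return t


def _dust_score(trips: np.ndarray) -> float:
    trips = trips[trips < 64]
    k = len(trips)
    if k < 2:
        return 0.0
    counts = np.bincount(trips, minlength=64)
    return float((counts * (counts - 1) // 2).sum()) / (k - 1)


def dust_mask(seq: str, config: AlignmentConfig | None = None) -> np.ndarray:
    """Boolean mask of positions inside low-complexity windows."""
    config = config or AlignmentConfig()
    a = encode(seq)
    mask = np.zeros(len(seq), dtype=bool)
    trips = _triplet_codes(a)
    w, step = config.dust_window, config.dust_window // 2
    if len(seq) <= 2:
        return mask
    for start in range(0, max(1, len(trips)), step):
        window = trips[start : start + w]
        if len(window) == 0:
            break
        if _dust_score(window) > config.dust_threshold:
            mask[start : start + w + 2] = True
    return mask


def is_low_complexity(seq: str, config: AlignmentConfig | None = None) -> bool:
    """True for mononucleotide runs, 1-3 bp tandem repeats and DUST failures."""
    config = config or AlignmentConfig()
    if not seq:
        raise ValueError("empty sequence")
    a = encode(seq)
    n = len(a)
    for period in (1, 2, 3):
        if n > 3 * period:
            frac = float(np.mean(a[period:] == a[:-period]))
            if frac >= 0.85:
                return True
    mask = dust_mask(seq, config)
    return bool(mask.mean() > 0.5)


# ---------------------------------------------------------------------------
# seeding
# ---------------------------------------------------------------------------


def _word_codes(a: np.ndarray, w: int) -> tuple[np.ndarray, np.ndarray]:
    """(codes, valid) for every window of length w; invalid if it has an N."""
    L = len(a) - w + 1
    if L <= 0:
        return np.empty(0, np.int64), np.empty(0, bool)
    codes = np.zeros(L, dtype=np.int64)
    valid = np.ones(L, dtype=bool)
    for j in range(w):
        seg = a[j : j + L]
        codes = codes * 4 + np.where(seg < 4, seg, 0).astype(np.int64)
        valid &= seg < 4
    return codes, valid


class SubjectIndex:
    """Sorted word index over one subject sequence, reusable across queries."""

    def __init__(self, seq: str, word_size: int = 7, name: str = "subject"):
        self.seq = seq.upper()
        self.name = name
        self.word_size = word_size
        self.length = len(seq)
        self.codes_arr = encode(self.seq)
        codes, valid = _word_codes(self.codes_arr, word_size)
        pos = np.nonzero(valid)[0]
        vals = codes[pos]
        order = np.argsort(vals, kind="stable")
        self.sorted_codes = vals[order]
        self.sorted_pos = pos[order].astype(np.int64)

    @cached_property
    def reverse(self) -> "SubjectIndex":
        return SubjectIndex(reverse_complement(self.seq), self.word_size,
                            name=self.name + "(-)")


@njit(cache=True)
def _extend_seeds(qa, sa, qps, sps, w, match, mismatch, xdrop, max_nrun, smin, out):
    """Ungapped x-drop extension of diagonal-sorted seeds.

    Seeds already covered by an extension on the same diagonal are skipped.
    N columns score as mismatches and extension stops at a run of
    ``max_nrun`` Ns.  Returns number of HSP rows written to ``out``
    (columns: qs, qe, ss, se, score, identities).
    """
    qlen = qa.shape[0]
    slen = sa.shape[0]
    n = qps.shape[0]
    m = 0
    prev_diag = np.int64(-(10 ** 15))
    covered_end = np.int64(-1)
    for k in range(n):
        qp = qps[k]
        sp = sps[k]
        d = sp - qp
        if d != prev_diag:
            prev_diag = d
            covered_end = -1
        if qp < covered_end:
            continue
        # right extension from seed end
        cur = 0
        best_r = 0
        ident_r = 0
        cur_ident = 0
        end_off = 0
        i = qp + w
        j = sp + w
        nrun = 0
        off = 0
        while i < qlen and j < slen:
            a = qa[i]
            b = sa[j]
            off += 1
            if a > 3 or b > 3:
                nrun += 1
                if nrun >= max_nrun:
                    break
                cur += mismatch
            elif a == b:
                nrun = 0
                cur += match
                cur_ident += 1
                if cur > best_r:
                    best_r = cur
                    ident_r = cur_ident
                    end_off = off
            else:
                nrun = 0
                cur += mismatch
            if best_r - cur > xdrop:
                break
            i += 1
            j += 1
        # left extension from seed start
        cur = 0
        best_l = 0
        ident_l = 0
        cur_ident = 0
        start_off = 0
        i = qp - 1
        j = sp - 1
        nrun = 0
        off = 0
        while i >= 0 and j >= 0:
            a = qa[i]
            b = sa[j]
            off += 1
            if a > 3 or b > 3:
                nrun += 1
                if nrun >= max_nrun:
                    break
                cur += mismatch
            elif a == b:
                nrun = 0
                cur += match
                cur_ident += 1
                if cur > best_l:
                    best_l = cur
                    ident_l = cur_ident
                    start_off = off
            else:
                nrun = 0
                cur += mismatch
            if best_l - cur > xdrop:
                break
            i -= 1
            j -= 1
        qs = qp - start_off
        qe = qp + w + end_off
        score = w * match + best_r + best_l
        covered_end = qe
        if score >= smin:
            out[m, 0] = qs
            out[m, 1] = qe
            out[m, 2] = qs + d
            out[m, 3] = qe + d
            out[m, 4] = score
            out[m, 5] = w + ident_r + ident_l
            m += 1
    return m


def _expand_ranges(lef: np.ndarray, rig: np.ndarray, order: np.ndarray,
                   qpos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    cnt = rig - lef
    total = int(cnt.sum())
    if total == 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    qrep = np.repeat(qpos, cnt)
    starts = np.repeat(lef, cnt)
    grp0 = np.repeat(np.cumsum(cnt) - cnt, cnt)
    sidx = order[starts + (np.arange(total) - grp0)]
    return qrep.astype(np.int64), sidx.astype(np.int64)


def _raw_hsps(qa: np.ndarray, index: SubjectIndex, config: AlignmentConfig,
              smin: int) -> np.ndarray:
    """Seed, sort by diagonal, extend.  Rows: qs,qe,ss,se,score,identities."""
    qcodes, qvalid = _word_codes(qa, config.word_size)
    qpos = np.nonzero(qvalid)[0]
    if len(qpos) == 0 or len(index.sorted_codes) == 0:
        return np.empty((0, 6), np.int64)
    vals = qcodes[qpos]
    lef = np.searchsorted(index.sorted_codes, vals, side="left")
    rig = np.searchsorted(index.sorted_codes, vals, side="right")
    qrep, srep = _expand_ranges(lef, rig, index.sorted_pos, qpos)
    if len(qrep) == 0:
        return np.empty((0, 6), np.int64)
    diag = srep - qrep
    order = np.lexsort((qrep, diag))
    qrep = qrep[order]
    srep = srep[order]
    out = np.empty((len(qrep), 6), np.int64)
    m = _extend_seeds(qa, index.codes_arr, qrep, srep, config.word_size,
                      config.match, config.mismatch, config.x_drop,
                      config.max_n_run, smin, out)
    return out[:m]


def _chain(rows: list[list[int]], config: AlignmentConfig) -> list[list[int]]:
    """Greedy chaining of collinear HSPs across small gaps (gapped step).

    Two HSPs merge when the query/subject gaps between them are non-negative
    and at most ``max_chain_gap``, and the merged score (affine penalty for
    the diagonal shift, mismatch cost for the residual unaligned stretch)
    beats both parts.  Merged length counts gap columns.
    """
    rows = sorted(rows, key=lambda r: (r[0], r[1]))
    out: list[list[int]] = []
    for r in rows:
        if out:
            c = out[-1]
            qgap = r[0] - c[1]
            sgap = r[2] - c[3]
            if 0 <= qgap <= config.max_chain_gap and 0 <= sgap <= config.max_chain_gap:
                shift = abs(qgap - sgap)
                pen = 0
                if shift > 0:
                    pen += config.gap_open + config.gap_extend * (shift - 1)
                pen += config.mismatch * min(qgap, sgap)
                merged_score = c[4] + r[4] + pen
                if merged_score > max(c[4], r[4]):
                    c[1] = r[1]
                    c[3] = r[3]
                    c[4] = merged_score
                    c[5] = c[5] + r[5]
                    c[6] = c[6] + r[6] + max(qgap, sgap)
                    continue
        out.append(r)
    return out


def local_align(query: str, subject: str | SubjectIndex,
                config: AlignmentConfig | None = None,
                q_id: str = "query", both_strands: bool = True) -> list[HSP]:
    """All significant local alignments of ``query`` against ``subject``.

    Returns HSPs with e-value <= ``config.evalue_cutoff``, both orientations
    (subject reverse-complemented for reverse hits; coordinates reported on
    the forward strand), sorted by score descending.  HSPs with more than
    half of their query columns inside low-complexity (DUST) windows are
    dropped when the filter is enabled.
    """
    config = config or AlignmentConfig()
    if not query:
        raise ValueError("empty query")
    if isinstance(subject, str):
        if not subject:
            raise ValueError("empty subject")
        subject = SubjectIndex(subject, config.word_size)
    elif subject.word_size != config.word_size:
        raise ValueError("subject index word size does not match config")

    qa = encode(query.upper())
    m_len, n_len = len(query), subject.length
    # smallest integer score that can pass the e-value cutoff
    smin = config.word_size * config.match
    while evalue(smin, m_len, n_len, config) > config.evalue_cutoff:
        smin += 1
    smin = max(smin, config.word_size * config.match)

    qmask = dust_mask(query, config) if config.filter_low_complexity else None

    hsps: list[HSP] = []
    strands = [("forward", subject)]
    if both_strands:
        strands.append(("reverse", subject.reverse))
    for orientation, idx in strands:
        raw = _raw_hsps(qa, idx, config, smin)
        # rows as lists: qs,qe,ss,se,score,identities,length
        rows = [[int(r[0]), int(r[1]), int(r[2]), int(r[3]), int(r[4]), int(r[5]),
                 int(r[1] - r[0])] for r in raw]
        rows = _chain(rows, config)
        for qs, qe, ss, se, score, idents, length in rows:
            ev = evalue(score, m_len, n_len, config)
            if ev > config.evalue_cutoff:
                continue
            if qmask is not None and length > 0:
                frac = float(qmask[qs:qe].mean()) if qe > qs else 0.0
                if frac > 0.5:
                    continue
            if orientation == "reverse":
                ss, se = subject.length - se, subject.length - ss
            hsps.append(HSP(q_id=q_id, s_id=subject.name, q_start=qs, q_end=qe,
                            s_start=ss, s_end=se, orientation=orientation,
                            length=length, identity=idents / length if length else 0.0,
                            score=score, evalue=ev))
    # drop HSPs contained in a higher-scoring one with the same orientation
    hsps.sort(key=lambda h: (-h.score, h.q_start, h.s_start, h.orientation))
    kept: list[HSP] = []
    for h in hsps:
        contained = False
        for g in kept:
            if (g.orientation == h.orientation and g.q_start <= h.q_start
                    and h.q_end <= g.q_end and g.s_start <= h.s_start
                    and h.s_end <= g.s_end):
                contained = True
                break
        kept.append(h) if not contained else None
        if len(kept) > 5000:
            break
    return kept


class GenomeIndex:
    """Per-chromosome subject indexes over a whole genome."""

    def __init__(self, genome, config: AlignmentConfig | None = None):
        config = config or AlignmentConfig()
        self.genome = genome
        self.word_size = config.word_size
        self.indexes = {name: SubjectIndex(seq, config.word_size, name=name)
                        for name, seq in genome.chromosomes.items()}

    def align(self, query: str, config: AlignmentConfig | None = None,
              q_id: str = "query") -> list[HSP]:
        """Query against every chromosome; s_id carries the chromosome name."""
        config = config or AlignmentConfig()
        out: list[HSP] = []
        for name in sorted(self.indexes):
            out.extend(local_align(query, self.indexes[name], config, q_id=q_id))
        out.sort(key=lambda h: (-h.score, h.s_id, h.s_start))
        return out


def read_blast_tab(path) -> list[HSP]:
    """Import externally computed hits from BLAST outfmt-6 tabular output."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            (qid, sid, pident, length, _mm, _go, qs, qe, ss, se, ev, score) = \
                line.rstrip("\n").split("\t")[:12]
            ss_i, se_i = int(ss), int(se)
            orientation = "forward" if se_i >= ss_i else "reverse"
            if orientation == "reverse":
                ss_i, se_i = se_i, ss_i
            out.append(HSP(q_id=qid, s_id=sid, q_start=int(qs) - 1, q_end=int(qe),
                           s_start=ss_i - 1, s_end=se_i, orientation=orientation,
                           length=int(length), identity=float(pident) / 100.0,
                           score=int(float(score)), evalue=float(ev)))
    return out
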