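"""PSPM motifs: ZOOPS EM discovery, redundancy filtering and log-odds scanning.

The family's conserved sequence blocks (the "LOGOs") are modelled as
position-specific probability matrices (PSPMs) of width 10-50 over the
20-letter alphabet.  Discovery uses an expectation-maximisation fit of the
ZOOPS site model (each sequence contributes zero or one occurrence):

* E step - posterior responsibility of every window of width ``w`` in every
  sequence, against a background of independent draws from ``background``;
  the prior probability that a sequence carries a site is ``gamma``.
* M step - MAP update of the matrix with a symmetric Dirichlet pseudocount
  (0.01 per cell) and maximum-likelihood update of ``gamma``.

The tracked objective is the observed-data log-likelihood (relative to the
all-background model) plus the Dirichlet log-prior; MAP-EM makes it
non-decreasing, which is asserted by the test suite.  Accepted motifs must
have at least ``min_sites`` sites, a mean per-column information content of
at least ``min_ic`` bits, and pass a BIC-style significance test (expected
log-likelihood ratio exceeding 0.5 * 19w * ln(n_sites), the matrix's free
parameters priced at the number of contributing sites); the significance
test is what rejects motifs "discovered" in featureless random sequence.
After convergence the alignment is probed with +/-1..2 column-shift moves
(the standard escape from EM phase-locking).  Accepted sites are masked
before the next motif is sought.
"""
from __future__ import annotations

import re
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import logsumexp
from scipy.stats import entropy, pearsonr

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
N_ALPHA = len(ALPHABET)
_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}

PSEUDOCOUNT = 0.01
MIN_WIDTH, MAX_WIDTH = 10, 50


def encode(sequence: str) -> np.ndarray:
    """Integer-encode a sequence; masked/unknown positions ('X') become -1."""
    return np.array([_INDEX.get(ch, -1) for ch in sequence], dtype=np.int64)


def uniform_background() -> np.ndarray:
    return np.full(N_ALPHA, 1.0 / N_ALPHA)


@dataclass
class PSPM:
    """A position-specific probability matrix.

    ``matrix`` has shape (width, 20), each row summing to 1; ``background``
    is the 20-vector used for log-odds scoring; ``n_sites`` is the number of
    sequences that contributed a site during discovery.
    """

    motif_id: str
    matrix: np.ndarray
    background: np.ndarray = field(default_factory=uniform_background)
    n_sites: int = 0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != N_ALPHA:
            raise ValueError(f"{self.motif_id}: matrix must be (width, {N_ALPHA})")
        if not (MIN_WIDTH <= self.width <= MAX_WIDTH):
            raise ValueError(
                f"{self.motif_id}: width {self.width} outside [{MIN_WIDTH}, {MAX_WIDTH}]"
            )
        sums = self.matrix.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError(f"{self.motif_id}: matrix rows must sum to 1")
        self.matrix /= sums[:, None]

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def ic_per_column(self) -> np.ndarray:
        """Bits per column relative to a uniform background:
        log2(20) - H(column)."""
        return np.log2(N_ALPHA) - entropy(self.matrix, base=2, axis=1)

    @property
    def total_ic(self) -> float:
        return float(self.ic_per_column.sum())

    @property
    def mean_ic(self) -> float:
        return float(self.ic_per_column.mean())

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.matrix.argmax(axis=1))

    def log_odds(self) -> np.ndarray:
        """log2(matrix / background), shape (width, 20)."""
        return np.log2(self.matrix) - np.log2(self.background)[None, :]

    @property
    def max_score(self) -> float:
        return float(self.log_odds().max(axis=1).sum())


@dataclass(frozen=True)
class MotifOccurrence:
    """One PSPM hit on one sequence (1-based start)."""

    motif_id: str
    sequence_id: str
    start: int
    score: float
    width: int
    region_label: str = ""

    @property
    def end(self) -> int:
        return self.start + self.width - 1


# ---------------------------------------------------------------------------
# ZOOPS EM


def _window_matrix(enc: np.ndarray, width: int) -> np.ndarray:
    """All width-windows of an encoded sequence as an (m, width) array."""
    if len(enc) < width:
        return np.empty((0, width), dtype=np.int64)
    return sliding_window_view(enc, width)


class _Corpus:
    """Precomputed window views for EM over one width."""

    def __init__(self, encoded: Sequence[np.ndarray], width: int):
        self.width = width
        self.windows: list[np.ndarray] = [_window_matrix(e, width) for e in encoded]
        self.n_seqs = len(encoded)

    def counts(self, seq_index: int, weights: np.ndarray) -> np.ndarray:
        """Weighted letter counts, shape (width, 20); masked positions are
        excluded."""
        win = self.windows[seq_index]
        w = self.width
        # bin = column * 21 + (letter + 1); letter -1 (mask) lands in bin 0 of
        # each column block and is dropped.
        bins = (np.arange(w)[None, :] * (N_ALPHA + 1)) + (win + 1)
        flat = np.bincount(
            bins.ravel(),
            weights=np.repeat(weights, w),
            minlength=w * (N_ALPHA + 1),
        ).reshape(w, N_ALPHA + 1)
        return flat[:, 1:]


def _site_log_ratios(corpus: _Corpus, log_ratio: np.ndarray) -> list[np.ndarray]:
    """Per sequence, the log-likelihood ratio (site vs background) of every
    window.  ``log_ratio`` is (width, 20) in nats; masked positions score 0."""
    w = corpus.width
    ext = np.concatenate([np.zeros((w, 1)), log_ratio], axis=1)  # mask column
    cols = np.arange(w)[None, :]
    return [
        ext[cols, win + 1].sum(axis=1) if win.size else np.empty(0)
        for win in corpus.windows
    ]


def _em_fit(
    corpus: _Corpus,
    init_matrix: np.ndarray,
    background: np.ndarray,
    gamma0: float = 0.5,
    max_iter: int = 200,
    tol: float = 1e-4,
) -> dict:
    """Run ZOOPS MAP-EM from one starting matrix.

    Returns the fitted matrix, gamma, per-sequence posteriors, the objective
    trace (relative log-likelihood + Dirichlet log-prior, nats) and the
    expected site log-likelihood ratio.
    """
    w = corpus.width
    matrix = init_matrix.copy()
    gamma = gamma0
    log_bg = np.log(background)
    trace: list[float] = []
    z_list: list[np.ndarray] = []
    expected_llr = 0.0

    for _ in range(max_iter):
        log_ratio = np.log(matrix) - log_bg[None, :]
        ratios = _site_log_ratios(corpus, log_ratio)

        loglik = 0.0
        z_list = []
        site_mass = 0.0
        expected_llr = 0.0
        counts = np.zeros((w, N_ALPHA))
        for i, scores in enumerate(ratios):
            m = len(scores)
            if m == 0:
                z_list.append(np.empty(0))
                loglik += np.log1p(-gamma) if gamma < 1 else -np.inf
                continue
            log_terms = np.concatenate(
                [[np.log1p(-gamma)], np.log(gamma / m) + scores]
            )
            norm = logsumexp(log_terms)
            loglik += norm
            z = np.exp(log_terms[1:] - norm)
            z_list.append(z)
            site_mass += z.sum()
            expected_llr += float(z @ scores)
            counts += corpus.counts(i, z)

        objective = loglik + PSEUDOCOUNT * np.log(matrix).sum()
        trace.append(float(objective))
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol:
            break

        matrix = counts + PSEUDOCOUNT
        matrix /= matrix.sum(axis=1, keepdims=True)
        gamma = min(max(site_mass / corpus.n_seqs, 1e-6), 1 - 1e-6)

    n_sites = sum(1 for z in z_list if z.size and z.sum() > 0.5)
    return {
        "matrix": matrix,
        "gamma": gamma,
        "z": z_list,
        "objective_trace": np.array(trace),
        "expected_llr": expected_llr,
        "n_sites": n_sites,
    }


def _seed_matrix(window: np.ndarray, width: int) -> np.ndarray:
    """Initial matrix from one substring: 0.6 on the observed letter."""
    matrix = np.full((width, N_ALPHA), 0.4 / (N_ALPHA - 1))
    for k, letter in enumerate(window):
        if letter >= 0:
            matrix[k, letter] = 0.6
        else:
            matrix[k] = 1.0 / N_ALPHA
    return matrix


def _width_schedule(widths: Sequence[int]) -> tuple[list[int], set[int]]:
    """Coarse grid (multiples of 5 within the requested widths, or all of
    them when the request is already small) plus the full allowed set."""
    allowed = sorted(set(int(w) for w in widths))
    coarse = [w for w in allowed if w % 5 == 0]
    if not coarse or len(allowed) <= 5:
        coarse = allowed
    return coarse, set(allowed)


def _shifted_matrix(matrix: np.ndarray, shift: int) -> np.ndarray:
    """Slide all columns by ``shift``, filling vacated columns uniformly."""
    w = matrix.shape[0]
    out = np.full_like(matrix, 1.0 / N_ALPHA)
    if shift >= 0:
        out[: w - shift] = matrix[shift:]
    else:
        out[-shift:] = matrix[:shift]
    return out


def _fit_width(
    corpus: _Corpus,
    background: np.ndarray,
    rng: np.random.Generator,
    n_restarts: int,
    max_iter: int,
    tol: float,
) -> dict | None:
    """Best-of-restarts EM fit for one width; restart seeds are substrings.

    The winning fit is probed with column-shift moves (re-running EM from a
    +/-1..2 shifted matrix) to escape phase-locked local optima."""
    pool = [
        (i, j)
        for i, win in enumerate(corpus.windows)
        for j in range(win.shape[0])
    ]
    if not pool:
        return None
    best: dict | None = None
    for _ in range(n_restarts):
        i, j = pool[int(rng.integers(len(pool)))]
        init = _seed_matrix(corpus.windows[i][j], corpus.width)
        fit = _em_fit(corpus, init, background, max_iter=max_iter, tol=tol)
        if best is None or fit["objective_trace"][-1] > best["objective_trace"][-1]:
            best = fit
    for _ in range(8):  # iterated hill-climb over phase shifts
        improved = False
        for shift in (-2, -1, 1, 2):
            init = _shifted_matrix(best["matrix"], shift)
            fit = _em_fit(corpus, init, background, max_iter=max_iter, tol=tol)
            if fit["objective_trace"][-1] > best["objective_trace"][-1] + 1e-9:
                best = fit
                improved = True
        if not improved:
            break
    return best


def discover_motifs(
    sequences: Sequence[str],
    widths: Iterable[int] = range(MIN_WIDTH, MAX_WIDTH + 1),
    max_motifs: int = 10,
    seed: int = 0,
    *,
    min_ic: float = 0.5,
    min_sites: int = 3,
    n_restarts: int = 10,
    max_iter: int = 200,
    tol: float = 1e-4,
    background: np.ndarray | None = None,
    motif_prefix: str = "m",
) -> list[PSPM]:
    """Iteratively discover ZOOPS motifs, masking accepted sites.

    The width search is coarse (multiples of 5) followed by a +/-2 refinement
    around the best width; widths are ranked by a BIC-adjusted expected
    log-likelihood ratio, ``E[LLR] - 0.5 * 19w * ln(n_sites)`` nats.
    Deterministic given ``seed``.

    Raises
    ------
    ValueError
        On fewer than 5 sequences or an empty/out-of-range width set.
    """
    sequences = list(sequences)
    if len(sequences) < 5:
        raise ValueError(f"need at least 5 sequences, got {len(sequences)}")
    width_list = sorted(set(int(w) for w in widths))
    if not width_list:
        raise ValueError("empty width range")
    if width_list[0] < MIN_WIDTH or width_list[-1] > MAX_WIDTH:
        raise ValueError(
            f"widths must lie in [{MIN_WIDTH}, {MAX_WIDTH}], got {width_list}"
        )
    bg = uniform_background() if background is None else np.asarray(background, float)
    rng = np.random.default_rng(seed)
    encoded = [encode(s.upper()) for s in sequences]
    coarse, allowed = _width_schedule(width_list)

    def quality(fit: dict, width: int) -> float:
        penalty = 0.5 * (N_ALPHA - 1) * width * np.log(max(fit["n_sites"], 2))
        return fit["expected_llr"] - penalty

    accepted: list[PSPM] = []
    for round_idx in range(max_motifs):
        fits: dict[int, dict] = {}
        for w in coarse:
            fit = _fit_width(
                _Corpus(encoded, w), bg, rng, n_restarts, max_iter, tol
            )
            if fit is not None:
                fits[w] = fit
        if not fits:
            break
        best_w = max(fits, key=lambda w: (quality(fits[w], w), -w))
        refine = [
            w
            for w in range(best_w - 2, best_w + 3)
            if w in allowed and w not in fits
        ]
        for w in refine:
            fit = _fit_width(
                _Corpus(encoded, w), bg, rng, n_restarts, max_iter, tol
            )
            if fit is not None:
                fits[w] = fit
        best_w = max(fits, key=lambda w: (quality(fits[w], w), -w))
        best = fits[best_w]

        pspm = PSPM(
            motif_id=f"{motif_prefix}{len(accepted) + 1}",
            matrix=best["matrix"],
            background=bg,
            n_sites=best["n_sites"],
        )
        significant = quality(best, best_w) > 0.0
        if not (significant and pspm.n_sites >= min_sites and pspm.mean_ic >= min_ic):
            break
        accepted.append(pspm)

        # Mask the winning site of every sequence with posterior site mass.
        for i, z in enumerate(best["z"]):
            if z.size and z.sum() > 0.5:
                start = int(z.argmax())
                encoded[i] = encoded[i].copy()
                encoded[i][start : start + best_w] = -1
    return accepted


# ---------------------------------------------------------------------------
# Redundancy filtering


def redundancy(a: PSPM, b: PSPM) -> float:
    """Best-offset mean per-column Pearson correlation between two PSPMs,
    over slides with at least 50% column overlap (of the shorter motif);
    -inf when no offset reaches the overlap requirement."""
    wa, wb = a.width, b.width
    need = int(np.ceil(0.5 * min(wa, wb)))
    best = -np.inf
    for offset in range(-(wb - 1), wa):
        lo_a, hi_a = max(0, offset), min(wa, offset + wb)
        if hi_a - lo_a < need:
            continue
        cols_a = a.matrix[lo_a:hi_a]
        cols_b = b.matrix[lo_a - offset : hi_a - offset]
        rs = []
        for ra, rb in zip(cols_a, cols_b):
            if np.std(ra) < 1e-12 or np.std(rb) < 1e-12:
                rs.append(1.0 if np.allclose(ra, rb) else 0.0)
            else:
                rs.append(pearsonr(ra, rb).statistic)
        best = max(best, float(np.mean(rs)))
    return best


def deduplicate(pspms: Sequence[PSPM], threshold: float = 0.85) -> list[PSPM]:
    """Drop the lower-information member of every redundant pair.

    Two PSPMs are redundant when :func:`redundancy` exceeds ``threshold``.
    Survivors keep their input order; on ties the earlier motif survives.
    """
    pspms = list(pspms)
    dropped: set[int] = set()
    for i in range(len(pspms)):
        if i in dropped:
            continue
        for j in range(i + 1, len(pspms)):
            if j in dropped:
                continue
            if redundancy(pspms[i], pspms[j]) > threshold:
                if pspms[j].total_ic > pspms[i].total_ic:
                    dropped.add(i)
                    break
                dropped.add(j)
    return [p for k, p in enumerate(pspms) if k not in dropped]


# ---------------------------------------------------------------------------
# Scanning


def scan_pspm(
    sequence: str,
    pspm: PSPM,
    threshold_fraction: float = 0.7,
    sequence_id: str = "query",
) -> list[MotifOccurrence]:
    """Report windows scoring at least ``threshold_fraction`` of the PSPM's
    maximum attainable log-odds score; overlapping hits of the same motif
    are resolved best-first.  A sequence shorter than the width yields no
    hits."""
    if not (0 < threshold_fraction <= 1):
        raise ValueError("threshold_fraction must be in (0, 1]")
    enc = encode(sequence.upper())
    win = _window_matrix(enc, pspm.width)
    if win.shape[0] == 0:
        return []
    lod = pspm.log_odds()
    ext = np.concatenate([np.zeros((pspm.width, 1)), lod], axis=1)
    scores = ext[np.arange(pspm.width)[None, :], win + 1].sum(axis=1)
    cutoff = threshold_fraction * pspm.max_score
    hits = [
        MotifOccurrence(
            motif_id=pspm.motif_id,
            sequence_id=sequence_id,
            start=j + 1,
            score=float(s),
            width=pspm.width,
        )
        for j, s in enumerate(scores)
        if s >= cutoff
    ]
    hits.sort(key=lambda h: (-h.score, h.start))
    chosen: list[MotifOccurrence] = []
    for h in hits:
        if all(h.end < c.start or h.start > c.end for c in chosen):
            chosen.append(h)
    return sorted(chosen, key=lambda h: h.start)


def scan_catalog(
    records: dict[str, str],
    pspms: Sequence[PSPM],
    threshold_fraction: float = 0.7,
) -> list[MotifOccurrence]:
    """Scan every sequence with every PSPM of a catalog."""
    out: list[MotifOccurrence] = []
    for seq_id, seq in records.items():
        for pspm in pspms:
            out.extend(scan_pspm(seq, pspm, threshold_fraction, sequence_id=seq_id))
    return out


# ---------------------------------------------------------------------------
# MEME minimal motif text format


def write_meme(pspms: Sequence[PSPM], path: str | Path) -> None:
    """Serialize a PSPM catalog in MEME minimal motif format."""
    lines = ["MEME version 4", "", f"ALPHABET= {ALPHABET}", ""]
    if pspms:
        bg = pspms[0].background
        lines.append("Background letter frequencies")
        lines.append(
            " ".join(f"{aa} {freq:.6f}" for aa, freq in zip(ALPHABET, bg))
        )
        lines.append("")
    for p in pspms:
        lines.append(f"MOTIF {p.motif_id}")
        lines.append(
            f"letter-probability matrix: alength= {N_ALPHA} w= {p.width} "
            f"nsites= {p.n_sites} E= 0"
        )
        for row in p.matrix:
            lines.append(" " + " ".join(f"{x:.6f}" for x in row))
        lines.append("")
    Path(path).write_text("\n".join(lines))


def read_meme(path: str | Path) -> list[PSPM]:
    """Parse a MEME minimal motif file back into PSPMs."""
    text = Path(path).read_text()
    bg = uniform_background()
    bg_match = re.search(
        r"Background letter frequencies\n([^\n]+)", text
    )
    if bg_match:
        tokens = bg_match.group(1).split()
        freqs = {tokens[i]: float(tokens[i + 1]) for i in range(0, len(tokens), 2)}
        bg = np.array([freqs.get(aa, 1.0 / N_ALPHA) for aa in ALPHABET])
    pspms = []
    motif_re = re.compile(
        r"MOTIF (\S+)\nletter-probability matrix:[^\n]*w= (\d+) nsites= (\d+)[^\n]*\n"
        r"((?: [^\n]+\n?)+)"
    )
    for m in motif_re.finditer(text):
        motif_id, width, n_sites = m.group(1), int(m.group(2)), int(m.group(3))
        rows = [
            [float(x) for x in line.split()]
            for line in m.group(4).strip().splitlines()
        ]
        matrix = np.array(rows[:width])
        pspms.append(
            PSPM(motif_id=motif_id, matrix=matrix, background=bg, n_sites=n_sites)
        )
    return pspms
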