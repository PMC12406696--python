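"""Profile-based homology search over candidate protein sets.

Each reference clade is turned into a position-specific log-odds profile
built from its aligned members. Candidate proteins are scanned with an
ungapped sliding alignment (the shorter of profile and sequence must be
fully covered), and raw bit scores are converted to E-values through an
extreme-value (Gumbel) calibration fitted to the maximal scores of random
background sequences, scaled to the size of the scanned database — the same
decision semantics (score → E-value → cutoff) as a profile-HMM search, with
a default reporting cutoff of 1e-30.

An optional adapter to a true profile-HMM engine (pyhmmer) is provided
behind the same :class:`Hit` contract; see :func:`search_profiles_hmmer`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats

from ._aminoacids import ALPHABET, BACKGROUND, encode, validate_sequence

logger = logging.getLogger(__name__)

__all__ = [
    "ProfileModel",
    "CalibrationParams",
    "Hit",
    "CalibrationError",
    "build_profile",
    "calibrate_evalues",
    "calibration_from_scores",
    "score_sequence",
    "search_profiles",
    "search_profiles_hmmer",
    "align_to_representative",
]

DEFAULT_EVALUE_CUTOFF = 1e-30


class CalibrationError(RuntimeError):
    """Raised when the random-score distribution cannot support a Gumbel fit."""


@dataclass(frozen=True)
class ProfileModel:
    """Position-specific scoring profile for one clade."""

    clade_label: str
    family: str
    #: L x 20 per-position log2-odds scores (bits).
    matrix: np.ndarray
    #: L x 20 per-position emission probabilities (each row sums to 1).
    probabilities: np.ndarray
    background: np.ndarray

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("profile must have at least one column")
        if not np.allclose(self.probabilities.sum(axis=1), 1.0):
            raise ValueError("emission rows must each sum to 1")
        if not math.isclose(float(self.background.sum()), 1.0, rel_tol=1e-9):
            raise ValueError("background must sum to 1")


@dataclass(frozen=True)
class CalibrationParams:
    """Gumbel tail parameters for one profile: P(max score > s) ~ kappa·exp(-lambda·s)."""

    lam: float
    log_kappa: float
    database_size: int = 1

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lambda must be positive")

    @property
    def kappa(self) -> float:
        return math.exp(self.log_kappa)

    def evalue(self, score: float, database_size: int | None = None) -> float:
        """Expected number of random sequences at or above ``score``."""
        n = self.database_size if database_size is None else database_size
        log_e = math.log(max(n, 1)) + self.log_kappa - self.lam * score
        # clamp to keep E strictly positive (a zero E-value would defeat
        # degenerate cutoffs) and finite
        return min(float(n), math.exp(min(max(log_e, -744.0), 700.0)))


@dataclass(frozen=True)
class Hit:
    query_id: str
    clade_label: str
    family: str
    score_bits: float
    e_value: float
    qstart: int  # 1-based inclusive on the query
    qend: int


def build_profile(
    aligned_members: Sequence[str],
    pseudocount_weight: float = 1.0,
    *,
    clade_label: str = "",
    family: str = "",
    max_gap_fraction: float = 0.5,
) -> ProfileModel:
    """Build a log-odds profile from an alignment of clade member sequences.

    Emission probabilities per retained column mix the observed residue
    frequencies with the background: ``(freq + w·background) / (1 + w)``
    with ``w`` the pseudocount weight; columns with more than
    ``max_gap_fraction`` gaps are dropped (match-column rule).
    """
    if not aligned_members:
        raise ValueError("need at least one aligned sequence")
    width = len(aligned_members[0])
    if any(len(s) != width for s in aligned_members):
        raise ValueError("ragged alignment: member sequences differ in length")
    if pseudocount_weight < 0:
        raise ValueError("pseudocount weight must be non-negative")
    for s in aligned_members:
        validate_sequence(s, allow_gaps=True, name="aligned member")

    rows = []
    for col in range(width):
        residues = [s[col] for s in aligned_members if s[col] != "-"]
        gap_fraction = 1.0 - len(residues) / len(aligned_members)
        if gap_fraction > max_gap_fraction:
            continue
        counts = np.zeros(len(ALPHABET))
        for r in residues:
            counts[ALPHABET.index(r)] += 1.0
        # frequency-based mixing keeps the profile invariant to duplicated
        # members: (f + w*background) / (1 + w)
        freqs = counts / counts.sum()
        probs = (freqs + pseudocount_weight * BACKGROUND) / (1.0 + pseudocount_weight)
        rows.append(probs)
    if not rows:
        raise ValueError("no match columns survive the gap-fraction rule")
    probabilities = np.array(rows)
    with np.errstate(divide="ignore"):
        matrix = np.log2(probabilities / BACKGROUND)
    matrix[probabilities == 0] = -50.0  # zero-probability emissions (w = 0 only)
    return ProfileModel(
        clade_label=clade_label,
        family=family,
        matrix=matrix,
        probabilities=probabilities,
        background=BACKGROUND.copy(),
    )


def score_sequence(profile: ProfileModel, seq: str) -> tuple[float, int, int]:
    """Best ungapped local alignment score of ``seq`` against the profile, in bits.

    The score is the maximal-scoring contiguous segment over all profile/query
    diagonals (the maximal-segment regime in which extreme-value E-value
    statistics apply). Returns ``(score, qstart, qend)`` with 1-based query
    coordinates of the best segment (``(0, 0)`` if the best segment is empty).
    """
    validate_sequence(seq, name="query")
    idx = encode(seq)
    L, n = profile.length, len(idx)
    v = profile.matrix[:, idx]  # L x n
    # Stack diagonals as columns of a band matrix: entry (j, i) of v goes to
    # row j, column i - j + (L - 1). Off-band cells are zero, which cannot
    # improve a maximal segment.
    band = np.zeros((L, L + n - 1))
    cols = np.arange(n)[None, :] + (L - 1 - np.arange(L))[:, None]
    band[np.arange(L)[:, None], cols] = v
    cs = np.cumsum(band, axis=0)
    prev_min = np.minimum.accumulate(np.vstack([np.zeros(L + n - 1), cs[:-1]]), axis=0)
    gains = cs - prev_min
    score = float(gains.max())
    if score <= 0.0:
        return max(score, 0.0), 0, 0
    j_end, c = np.unravel_index(int(np.argmax(gains)), gains.shape)
    col = cs[:, c]
    lower = np.concatenate([[0.0], col[:j_end]])
    j_start = int(np.argmin(lower))  # segment starts at row j_start
    i_start = int(j_start + c - (L - 1))
    i_end = int(j_end + c - (L - 1))
    return score, i_start + 1, i_end + 1


def calibrate_evalues(
    profile: ProfileModel,
    n_random: int = 1000,
    seed: int = 42,
    length_dist: Callable[[np.random.Generator], int] | None = None,
) -> CalibrationParams:
    """Fit a Gumbel law to max scores of random background sequences.

    ``length_dist`` draws one sequence length per call (default: normal with
    mean 300, sd 60, floored at 30 — typical of predicted metagenome
    proteins). Deterministic given ``seed``.
    """
    if n_random < 100:
        raise ValueError("n_random must be at least 100 for a stable tail fit")
    rng = np.random.default_rng(seed)
    if length_dist is None:
        length_dist = lambda r: max(30, int(round(r.normal(300.0, 60.0))))  # noqa: E731
    maxima = np.empty(n_random)
    for i in range(n_random):
        length = length_dist(rng)
        seq_idx = rng.choice(len(ALPHABET), size=length, p=BACKGROUND)
        seq = "".join(ALPHABET[j] for j in seq_idx)
        maxima[i], _, _ = score_sequence(profile, seq)
    return calibration_from_scores(maxima)


def calibration_from_scores(maxima: np.ndarray, database_size: int = 1) -> CalibrationParams:
    """Gumbel-fit a sample of per-sequence maximal scores into tail parameters.

    Shifting all scores by a constant leaves lambda unchanged; the shift is
    absorbed into kappa.
    """
    maxima = np.asarray(maxima, dtype=float)
    if np.ptp(maxima) < 1e-12:
        raise CalibrationError("degenerate score distribution: zero variance")
    loc, scale = stats.gumbel_r.fit(maxima)
    lam = 1.0 / scale
    return CalibrationParams(lam=lam, log_kappa=loc * lam, database_size=database_size)


def search_profiles(
    profiles: Sequence[ProfileModel],
    proteins: Mapping[str, str],
    cutoff: float = DEFAULT_EVALUE_CUTOFF,
    calibration: Mapping[str, CalibrationParams] | CalibrationParams | None = None,
) -> list[Hit]:
    """Scan a protein set with clade profiles, reporting hits with E ≤ cutoff.

    The cutoff is applied per profile-query pair; each query then reports its
    best clade per family. Hits are sorted by ascending E-value (score and
    query id break ties).
    """
    if calibration is None:
        raise ValueError("calibration parameters are required for E-values")
    if not proteins:
        logger.warning("empty protein database: no hits")
        return []
    db_size = len(proteins)
    best: dict[tuple[str, str], Hit] = {}
    for profile in profiles:
        if isinstance(calibration, CalibrationParams):
            calib = calibration
        else:
            if profile.clade_label not in calibration:
                raise KeyError(f"missing calibration for clade {profile.clade_label!r}")
            calib = calibration[profile.clade_label]
        for qid, seq in proteins.items():
            score, qstart, qend = score_sequence(profile, seq)
            e_value = calib.evalue(score, db_size)
            if e_value > cutoff:
                continue
            hit = Hit(qid, profile.clade_label, profile.family, score, e_value, qstart, qend)
            key = (qid, profile.family)
            prev = best.get(key)
            if prev is None or (hit.e_value, -hit.score_bits) < (prev.e_value, -prev.score_bits):
                best[key] = hit
    return sorted(best.values(), key=lambda h: (h.e_value, -h.score_bits, h.query_id))


def search_profiles_hmmer(
    alignments: Mapping[str, tuple[str, Sequence[str]]],
    proteins: Mapping[str, str],
    cutoff: float = DEFAULT_EVALUE_CUTOFF,
) -> list[Hit]:
    """Optional external backend: true profile-HMM search via pyhmmer.

    ``alignments`` maps clade label -> (family, aligned member sequences).
    Produces hits under the same contract as :func:`search_profiles`.
    """
    import pyhmmer

    abc = pyhmmer.easel.Alphabet.amino()
    builder = pyhmmer.plan7.Builder(abc)
    background = pyhmmer.plan7.Background(abc)
    hmms = []
    fam_of = {}
    for clade_label, (family, members) in alignments.items():
        fam_of[clade_label] = family
        if len(members) == 1:
            seq = pyhmmer.easel.TextSequence(
                name=clade_label.encode(), sequence=members[0]
            ).digitize(abc)
            hmm, _, _ = builder.build(seq, background)
        else:
            msa = pyhmmer.easel.TextMSA(
                name=clade_label.encode(),
                sequences=[
                    pyhmmer.easel.TextSequence(name=f"m{i}".encode(), sequence=s)
                    for i, s in enumerate(members)
                ],
            ).digitize(abc)
            hmm, _, _ = builder.build_msa(msa, background)
        hmms.append(hmm)
    targets = [
        pyhmmer.easel.TextSequence(name=qid.encode(), sequence=seq).digitize(abc)
        for qid, seq in proteins.items()
    ]
    best: dict[tuple[str, str], Hit] = {}
    def _name(raw) -> str:
        return raw.decode() if isinstance(raw, bytes) else str(raw)

    for top in pyhmmer.hmmsearch(hmms, targets, E=max(cutoff, 1e-300), Z=len(proteins)):
        clade_label = _name(top.query.name)
        family = fam_of[clade_label]
        for h in top:
            if h.evalue > cutoff:
                continue
            dom = h.best_domain
            hit = Hit(
                _name(h.name),
                clade_label,
                family,
                float(h.score),
                float(h.evalue),
                int(dom.env_from),
                int(dom.env_to),
            )
            key = (hit.query_id, family)
            prev = best.get(key)
            if prev is None or (hit.e_value, -hit.score_bits) < (prev.e_value, -prev.score_bits):
                best[key] = hit
    return sorted(best.values(), key=lambda h: (h.e_value, -h.score_bits, h.query_id))


def align_to_representative(candidate: str, representative: str):
    """Global alignment of a candidate against a clade representative.

    Returns a :class:`phytascan._pairwise.PairwiseAlignment` whose
    ``map_a_to_b``/``project`` methods map 1-based representative positions
    onto the candidate (``None``/extrapolated where the candidate is gapped).
    """
    from ._pairwise import align_global

    return align_global(representative, candidate)
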