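"""Position weight matrices: log-odds scoring and sequence sampling.

A PWM is an (L, 4) array of per-position base probabilities in A,C,G,T
order. Scores are log2 likelihood ratios against a background composition,
the same quantity motif scanners report for ranking binding sites.
"""

from __future__ import annotations

import numpy as np

from .genome import BASE_TO_CODE, CODE_TO_BASE, revcomp

__all__ = [
    "pwm_log_odds_score",
    "pwm_from_consensus",
    "sample_from_pwm",
    "score_sites",
]

_UNIFORM = np.full(4, 0.25)


def _validate_pwm(pwm: np.ndarray) -> np.ndarray:
    pwm = np.asarray(pwm, dtype=float)
    if pwm.ndim != 2 or pwm.shape[1] != 4:
        raise ValueError("PWM must have shape (L, 4)")
    if not np.allclose(pwm.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("PWM columns must be probability distributions")
    return pwm


def pwm_log_odds_score(pwm: np.ndarray, sequence: str,
                       background: np.ndarray | None = None) -> float:
    """Sum over positions of log2(p_pos(base)/bg(base)), in bits.

    An N base contributes 0. Sequence length must equal the PWM length.
    """
    pwm = _validate_pwm(pwm)
    if len(sequence) != len(pwm):
        raise ValueError(f"sequence length {len(sequence)} != PWM length {len(pwm)}")
    bg = _UNIFORM if background is None else np.asarray(background, dtype=float)
    codes = BASE_TO_CODE[np.frombuffer(sequence.upper().encode(), dtype=np.uint8)]
    score = 0.0
    for i, c in enumerate(codes):
        if c > 3:
            continue
        score += np.log2(pwm[i, c] / bg[c])
    return float(score)


def pwm_from_consensus(consensus: str, match_prob: float = 0.97) -> np.ndarray:
    """Near-deterministic PWM for a consensus string (other bases share the rest)."""
    codes = BASE_TO_CODE[np.frombuffer(consensus.upper().encode(), dtype=np.uint8)]
    if (codes > 3).any():
        raise ValueError(f"non-ACGT consensus {consensus!r}")
    pwm = np.full((len(codes), 4), (1.0 - match_prob) / 3.0)
    pwm[np.arange(len(codes)), codes] = match_prob
    return pwm


def sample_from_pwm(pwm: np.ndarray, rng: np.random.Generator) -> str:
    """Draw one sequence from the PWM's per-position distributions."""
    pwm = _validate_pwm(pwm)
    codes = [rng.choice(4, p=row) for row in pwm]
    return "".join(CODE_TO_BASE[codes])


def score_sites(pwm: np.ndarray, genome, siteset,
                background: np.ndarray | None = None):
    """Assign log-odds scores to every site, reading the motif-strand sequence."""
    scores = []
    for r in siteset.sites.itertuples():
        seq = genome.sequence(r.chrom, int(r.start), int(r.end))
        if r.strand == "-":
            seq = revcomp(seq)
        scores.append(pwm_log_odds_score(pwm, seq, background))
    out = siteset.sites.copy()
    out["score"] = scores
    return siteset._replace(out)
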