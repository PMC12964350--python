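"""Elongated/bent posture classification from the ellipse axis ratio.

A crawling larva is long and thin (large major/minor ratio R); during a
head cast the body folds and R drops.  Because absolute R varies with
animal size and optics, each track is standardised to z-scores of its own
R distribution and thresholded at a fixed number of standard deviations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PostureConfig", "ratio_zscores", "classify_state", "state_runs"]


@dataclass(frozen=True)
class PostureConfig:
    """Posture-classifier settings.

    z_threshold
        Cut on the per-track z-score of R, in standard deviations
        (default 0.8).
    bent_direction
        Which tail of the z distribution is called *bent*: ``"above"``
        flags frames with ``z >= z_threshold``; ``"below"`` flags
        ``z <= -z_threshold``.  Geometrically a bent body has a *smaller*
        axis ratio, which corresponds to ``"below"``; both conventions
        are exposed because sign conventions differ between setups.
    """

    z_threshold: float = 0.8
    bent_direction: str = "above"

    def __post_init__(self) -> None:
        if not np.isfinite(self.z_threshold):
            raise ValueError("z_threshold must be finite")
        if self.bent_direction not in ("above", "below"):
            raise ValueError("bent_direction must be 'above' or 'below'")


def ratio_zscores(ratios) -> np.ndarray:
    """Standardise a per-track R series to z-scores.

    Uses the population standard deviation over all frames of the track.
    A zero-variance series maps to all-zero z (every frame classified by
    the threshold sign as not bent).

    Raises
    ------
    ValueError
        For series shorter than 2 frames (posture undefined).
    """
    r = np.asarray(ratios, dtype=float)
    if r.ndim != 1 or len(r) < 2:
        raise ValueError("need at least 2 frames to standardise R")
    if not np.all(np.isfinite(r)):
        raise ValueError("R series contains non-finite values")
    sd = r.std()  # population sd (ddof=0)
    if sd == 0:
        return np.zeros_like(r)
    return (r - r.mean()) / sd


def classify_state(z, config: PostureConfig = PostureConfig()) -> np.ndarray:
    """Classify z-scores into ``"bent"`` / ``"elongated"`` states.

    The bent cut is inclusive (``z >= threshold`` for direction
    ``"above"``, ``z <= -threshold`` for ``"below"``).
    """
    z = np.asarray(z, dtype=float)
    if config.bent_direction == "above":
        bent = z >= config.z_threshold
    else:
        bent = z <= -config.z_threshold
    return np.where(bent, "bent", "elongated").astype(object)


def state_runs(states) -> list[tuple[str, int, int]]:
    """Maximal runs of identical states as ``(state, start, end)`` tuples.

    ``start``/``end`` are inclusive 0-based frame offsets; concatenating
    the runs reproduces the input partition.
    """
    states = list(states)
    if not states:
        return []
    runs = []
    start = 0
    for i in range(1, len(states)):
        if states[i] != states[i - 1]:
            runs.append((states[start], start, i - 1))
            start = i
    runs.append((states[start], start, len(states) - 1))
    return runs
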