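"""Small reporting arithmetic shared across output tables."""

from __future__ import annotations

__all__ = ["round_half_away", "proportion"]


def round_half_away(value: float, decimals: int = 1) -> float:
    """Round half away from zero (the convention used in the output tables).

    Python's builtin round() is banker's rounding; published
    pharmacovigilance tables round 0.05 -> 0.1, hence this helper.
    """
    scale = 10 ** decimals
    scaled = value * scale
    # nudge by a relative epsilon so float artefacts like 18.849999...99
    # representing an exact half still round as halves
    eps = abs(scaled) * 1e-12
    if scaled >= 0:
        return int(scaled + 0.5 + eps) / scale
    return -int(-scaled + 0.5 + eps) / scale


def proportion(numerator: int, denominator: int, decimals: int = 1) -> float:
    """Percent share 100*num/den, rounded half away from zero.

    Raises ValueError on a zero denominator rather than returning NaN so
    broken table arithmetic fails loudly.
    """
    if denominator == 0:
        raise ValueError("proportion undefined for zero denominator")
    return round_half_away(100.0 * numerator / denominator, decimals)
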