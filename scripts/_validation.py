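"""Brute-force n-back block validation used by the acceptance script."""

from __future__ import annotations


def block_violations(block, config) -> list[str]:
    """Re-check every block invariant directly from the definition."""
    v = []
    n = block.level
    stim = list(block.stimuli)
    targ = list(block.is_target)
    if len(stim) != config.critical_screens + n or len(targ) != len(stim):
        return ["wrong length"]
    if sum(targ) != config.targets_per_block:
        v.append(f"{sum(targ)} targets")
    if any(targ[:n]):
        v.append("target in lead-in")
    for i in range(n, len(stim)):
        repeat = stim[i] == stim[i - n]
        if targ[i] and not repeat:
            v.append(f"target at {i} is not a repeat")
        if not targ[i] and repeat:
            v.append(f"non-target at {i} repeats the n-back stimulus")
    if any(s < 0 or s >= config.alphabet_size for s in stim):
        v.append("stimulus outside alphabet")
    return v
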