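"""Independent brute-force oracle for prominence-based peak selection."""

import numpy as np


def brute_force_prominences(y):
    """Topographic prominence by definition: scan to the nearest higher
    ground on each side; base = the minimum encountered on that side;
    prominence = peak - max(left base, right base)."""
    peaks = [i for i in range(1, len(y) - 1) if y[i - 1] < y[i] >= y[i + 1]]
    out = []
    for i in peaks:
        bases = []
        for rng in (range(i - 1, -1, -1), range(i + 1, len(y))):
            base = y[i]
            for j in rng:
                if y[j] > y[i]:
                    break
                base = min(base, y[j])
            bases.append(base)
        out.append((i, y[i] - max(bases)))
    return out


def brute_force_detect(y, params, min_samples):
    """The selection rule applied literally: greedy suppression by height
    within the minimum separation over all local maxima, then the
    prominence floor.  Returns surviving sample indices."""
    prom = dict(brute_force_prominences(y))
    order = sorted(prom, key=lambda i: -y[i])
    kept = []
    for i in order:
        if all(abs(i - j) >= min_samples for j in kept):
            kept.append(i)
    thr = params.min_prominence_frac * (np.max(y) - np.min(y))
    return sorted(i for i in kept if prom[i] >= thr)
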