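"""Brute-force concordance-index oracle used by the reproduction script.

Deliberately independent of the package implementation: plain Python
loops over ordered pairs with the explicit evaluability rule.
"""


def brute_force_cindex(risk, time, event):
    conc = pairs = 0.0
    n = len(risk)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if event[i] == 1 and (
                time[i] < time[j] or (time[i] == time[j] and event[j] == 0)
            ):
                pairs += 1
                if risk[i] > risk[j]:
                    conc += 1
                elif risk[i] == risk[j]:
                    conc += 0.5
    if pairs == 0:
        raise ValueError("no evaluable pairs")
    return conc / pairs
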