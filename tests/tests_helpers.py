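"""Shared helpers for building labelled sample metadata in tests."""

from olivescreen.simulate import SampleTruth


def make_labelled_truths(n_evoo: int, n_voo: int, n_loo: int):
    truths = []
    i = 0
    for cat, n in (("EVOO", n_evoo), ("VOO", n_voo), ("LOO", n_loo)):
        for _ in range(n):
            i += 1
            if cat == "EVOO":
                truths.append(SampleTruth(f"S{i:04d}", cat, fruity_median=4.0))
            else:
                truths.append(SampleTruth(
                    f"S{i:04d}", cat, mpd="rancid",
                    defect_median=2.0 if cat == "VOO" else 5.0,
                    fruity_median=1.0))
    return truths
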