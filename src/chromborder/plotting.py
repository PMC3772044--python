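"""Minimal line-plot helper for signal profiles."""

from __future__ import annotations

from .profiles import SignalProfile


def plot_profile(profile: SignalProfile, ax=None, **kwargs):
    """Plot a SignalProfile as a line; returns the matplotlib axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(profile.axis, profile.values, **kwargs)
    ax.set_xlabel("offset / bin")
    ax.set_ylabel("mean signal")
    return ax
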