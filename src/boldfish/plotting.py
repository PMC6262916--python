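"""Optional figure helpers (requires matplotlib: ``pip install boldfish[plot]``).

Regenerates the standard result panels: trait-versus-age curves with ±1 SD
bands per gear-selectivity scenario, and reference-age traits against the
sweep axis.
"""

from __future__ import annotations

import numpy as np

from .experiments import SweepResult

_TRAIT_LABELS = {
    "length": "length-at-age (cm)",
    "phi": "foraging strategy φ",
    "natural_mortality": "natural mortality (1/yr)",
    "gsi": "GSI",
}


def plot_trait_by_age(sweep: SweepResult, trait: str, ax=None, scenarios=None):
    """Mean ± SD of a trait against age, one line per scenario."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    keys = scenarios if scenarios is not None else list(sweep.summaries)
    for key in keys:
        summ = sweep.summaries[key]
        sub = summ.by_age[summ.by_age.trait == trait]
        ax.plot(sub.age, sub["mean"], label=f"{sweep.axis}={key}")
        ax.fill_between(sub.age, sub["mean"] - sub.sd, sub["mean"] + sub.sd,
                        alpha=0.2)
    if sweep.baseline is not None:
        sub = sweep.baseline.by_age[sweep.baseline.by_age.trait == trait]
        ax.plot(sub.age, sub["mean"], "k--", label="unfished")
    ax.set_xlabel("age (years)")
    ax.set_ylabel(_TRAIT_LABELS.get(trait, trait))
    ax.legend(fontsize="small")
    return ax


def plot_reference_age_panel(sweep: SweepResult, traits=("phi", "natural_mortality",
                                                         "length", "gsi")):
    """Reference-age trait values against the swept axis, one subplot each."""
    import matplotlib.pyplot as plt

    tab = sweep.reference_table().sort_values(sweep.axis)
    fig, axes = plt.subplots(1, len(traits), figsize=(3.2 * len(traits), 3))
    for ax, trait in zip(np.atleast_1d(axes), traits):
        ax.plot(tab[sweep.axis], tab[trait], "o-")
        ax.set_xlabel(sweep.axis)
        ax.set_ylabel(_TRAIT_LABELS.get(trait, trait)
                      + f" @ age {sweep.reference_age}")
    fig.tight_layout()
    return fig
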