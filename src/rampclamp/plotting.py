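"""Overlay plot of VC curve and CC run in the (I, V) plane."""

from __future__ import annotations

LABEL_COLORS = {
    ("stable", "none"): "tab:blue",
    ("unstable", "slope"): "saddlebrown",
    ("unstable", "oscillation-evidence"): "tab:red",
    ("undetermined", "none"): "gold",
}


def plot_diagram(diag, ax=None):
    """Render the labeled VC curve with the CC overlay; returns the axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 5))
    c = diag.curve
    ax.plot(c.I_raw, c.Vh, lw=0.2, color="lightblue", alpha=0.6, label="raw Ivc")
    lab = diag.labeling
    for seg in lab.segments(c.Vh, c.I_sm):
        sel = (c.Vh >= seg["Vh_mV"][0]) & (c.Vh <= seg["Vh_mV"][1])
        color = LABEL_COLORS.get((seg["label"], seg["basis"]), "gray")
        ax.plot(c.I_sm[sel], c.Vh[sel], lw=2, color=color)
    ax.plot(diag.cc_I, diag.cc_V_sm, lw=0.5, color="tab:orange", label="CC run")
    if diag.envelope is not None:
        ax.plot(diag.envelope.I, diag.envelope.V_min, "k--", lw=0.8)
        ax.plot(diag.envelope.I, diag.envelope.V_max, "k--", lw=0.8)
    for v, i in lab.folds:
        ax.plot(i, v, "ks", ms=6, mfc="none")
    for v, i in lab.hopf:
        ax.plot(i, v, "k*", ms=10)
    if diag.I_db is not None:
        ax.axvline(diag.I_db, color="k", ls=":", lw=0.8)
    ax.set_xlabel("I (pA)")
    ax.set_ylabel("V (mV)")
    ax.legend(loc="best", fontsize=8)
    return ax
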