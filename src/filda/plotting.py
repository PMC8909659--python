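"""Optional basic plots (requires matplotlib, installed separately)."""

from __future__ import annotations

from .spectra import SpectraSet

__all__ = ["plot_spectra", "plot_scores"]


def _plt():
    try:
        import matplotlib.pyplot as plt
    except ImportError as exc:  # pragma: no cover
        raise ImportError("plotting requires matplotlib (pip install filda[plot])") from exc
    return plt


def plot_spectra(s: SpectraSet, ax=None, max_per_class: int = 10):
    """Overlay absorbance curves, coloured by class."""
    plt = _plt()
    ax = ax or plt.gca()
    for c in s.classes:
        idx = [i for i in range(s.n_samples) if s.labels[i] == c][:max_per_class]
        for j, i in enumerate(idx):
            ax.plot(s.wavelengths, s.absorbance[i], color=f"C{c}", alpha=0.6,
                    label=f"class {c}" if j == 0 else None)
    ax.set_xlabel("wavelength (nm)")
    ax.set_ylabel("absorbance")
    ax.legend()
    return ax


def plot_scores(scores: SpectraSet, ax=None, dims=(0, 1)):
    """Scatter of two score/DV dimensions, coloured by class."""
    plt = _plt()
    ax = ax or plt.gca()
    i, j = dims
    for c in scores.classes:
        mask = scores.labels == c
        ax.scatter(scores.absorbance[mask, i], scores.absorbance[mask, j],
                   s=14, label=f"class {c}")
    ax.set_xlabel(f"component {i + 1}")
    ax.set_ylabel(f"component {j + 1}")
    ax.legend()
    return ax
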