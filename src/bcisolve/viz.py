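"""Optional plots of increment variation across structures or charge methods.

Plot artifacts never affect numeric outputs; matplotlib is imported
lazily so headless batch runs without --plots pay nothing.
"""

from __future__ import annotations

from pathlib import Path

from .solver import BciSolution

__all__ = ["plot_bci_variation"]


def plot_bci_variation(solutions: list[BciSolution], out_dir) -> list[Path]:
    """One histogram per bond type of omega across solutions; returns paths."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    values: dict = {}
    for sol in solutions:
        for key, w in sol.omega.items():
            values.setdefault(key, []).append(w)
    paths: list[Path] = []
    for key in sorted(values):
        fig, ax = plt.subplots(figsize=(5, 3.5))
        v = values[key]
        ax.hist(v, bins=min(20, max(5, len(v))), edgecolor="black")
        ax.set_xlabel(f"bci {key} (e)")
        ax.set_ylabel("count")
        ax.set_title(f"{key}: n={len(v)}")
        fig.tight_layout()
        path = out_dir / f"bci_{key.type_lo}_{key.type_hi}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        paths.append(path)
    return paths
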