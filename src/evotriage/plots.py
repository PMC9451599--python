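"""Score visualisation: SR against expression, flagged genes labelled."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def sr_vs_expression(
    scores: pd.DataFrame,
    expression: pd.Series,
    out: str | Path,
    title: str = "",
    flag: float = 1.0,
) -> Path:
    """Scatter of SR vs expression (log2); genes with |SR| >= flag are
    coloured by direction and labelled with their symbol."""
    out = Path(out)
    df = scores.join(expression.rename("expression_log2_plot"), how="inner")
    fig, ax = plt.subplots(figsize=(7, 5))
    neutral = df[df["sr"].abs() < flag]
    conserved = df[df["sr"] <= -flag]
    over = df[df["sr"] >= flag]
    ax.scatter(neutral["expression_log2_plot"], neutral["sr"], s=8, c="#b0b0b0", label="background")
    ax.scatter(conserved["expression_log2_plot"], conserved["sr"], s=14, c="#c0392b", label="conserved")
    ax.scatter(over["expression_log2_plot"], over["sr"], s=14, c="#27ae60", label="over-mutated")
    for sym, row in pd.concat([conserved, over]).iterrows():
        ax.annotate(str(sym), (row["expression_log2_plot"], row["sr"]), fontsize=6, alpha=0.8)
    ax.axhline(flag, ls="--", lw=0.7, c="k")
    ax.axhline(-flag, ls="--", lw=0.7, c="k")
    ax.set_xlabel("expression (log2 counts)")
    ax.set_ylabel("standardized residual (SR)")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return out
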