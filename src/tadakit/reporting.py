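"""Cross-sample summaries: correlation matrices and gene-class composition."""

from __future__ import annotations

import numpy as np
import pandas as pd


def correlation_matrix(matrix: pd.DataFrame, method: str = "pearson") -> pd.DataFrame:
    """Pairwise column correlation over rows complete in both columns.

    Symmetric with unit diagonal.  Columns with zero variance get NaN as
    the undefined marker against every other column (their diagonal stays
    1 by the self-correlation convention).
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 columns")
    if matrix.shape[0] < 3:
        raise ValueError("need at least 3 rows")
    cols = list(matrix.columns)
    if len(set(cols)) != len(cols):
        raise ValueError("duplicate column labels")
    n = len(cols)
    out = np.full((n, n), np.nan)
    for i in range(n):
        out[i, i] = 1.0
        for j in range(i + 1, n):
            pair = matrix.iloc[:, [i, j]].dropna()
            x = pair.iloc[:, 0].to_numpy(dtype=float)
            y = pair.iloc[:, 1].to_numpy(dtype=float)
            if x.size < 2 or np.std(x) == 0 or np.std(y) == 0:
                continue  # undefined stays NaN
            if method == "spearman":
                x = pd.Series(x).rank().to_numpy()
                y = pd.Series(y).rank().to_numpy()
            r = np.corrcoef(x, y)[0, 1]
            out[i, j] = out[j, i] = r
    return pd.DataFrame(out, index=cols, columns=cols)


def class_composition(
    gene_sets: dict[str, set[str] | list[str]],
    class_map: dict[str, str],
    classes: tuple[str, ...] = ("TF", "ncRNA", "other"),
) -> pd.DataFrame:
    """Per gene set, counts and fractions by gene class.

    Genes missing from the class map count as 'other'; classes outside
    ``classes`` are folded into 'other'.  Fractions of an empty set are
    NaN (undefined marker).
    """
    rows = []
    for name in sorted(gene_sets):
        genes = gene_sets[name]
        counts = {c: 0 for c in classes}
        for g in genes:
            c = class_map.get(g, "other")
            counts[c if c in counts else "other"] += 1
        total = sum(counts.values())
        row = {"set": name, "total": total}
        for c in classes:
            row[f"n_{c}"] = counts[c]
            row[f"frac_{c}"] = counts[c] / total if total else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
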