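"""Reading and writing the package's plain-text formats.

Response matrices and Q-matrices travel as CSV/TSV with a header row (an
optional leading examinee-identifier column is detected and dropped for
response files).  Hierarchy specifications are YAML mappings with ``K`` and
either a ``preset`` name or a ``prerequisites`` pair list, e.g.::

    K: 3
    prerequisites: [[1, 2], [2, 3]]
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .hierarchy import AttributeHierarchy, hierarchy_preset
from .model import validate_qmatrix

__all__ = [
    "read_responses",
    "read_qmatrix",
    "read_hierarchy",
    "write_fit_json",
    "write_posteriors",
    "write_covariance",
]


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    return pd.read_csv(path, sep=sep)


def read_responses(path) -> np.ndarray:
    """Binary N x J response matrix from CSV/TSV; a non-binary first column
    is treated as an examinee identifier and dropped."""
    df = _read_table(path)
    first = df.iloc[:, 0]
    if df.shape[1] > 1 and not first.isin([0, 1]).all():
        df = df.iloc[:, 1:]
    X = df.to_numpy()
    if not np.isin(X, (0, 1)).all():
        raise ValueError(f"{path}: responses must be binary")
    return X.astype(np.int8)


def read_qmatrix(path) -> np.ndarray:
    """Binary J x K Q-matrix from CSV/TSV."""
    return validate_qmatrix(_read_table(path).to_numpy())


def read_hierarchy(path) -> AttributeHierarchy:
    """Attribute hierarchy from a YAML config (preset name or pair list)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    K = int(cfg["K"])
    if "preset" in cfg:
        return hierarchy_preset(cfg["preset"], K)
    pairs = frozenset((int(a), int(b)) for a, b in cfg.get("prerequisites", []))
    return AttributeHierarchy(K=K, prerequisites=pairs, name=str(cfg.get("name", "custom")))


def write_fit_json(fit, path) -> None:
    with open(path, "w") as fh:
        json.dump(fit.to_dict(), fh, indent=2)


def write_posteriors(fit, path) -> None:
    cols = ["".join(map(str, p)) for p in fit.space.patterns]
    pd.DataFrame(fit.posterior, columns=cols).to_csv(path, index=False)


def write_covariance(cov, path) -> None:
    names = []
    for tag in cov.param_index:
        if tag[0] == "item":
            names.append(f"P[item{tag[1] + 1},g{tag[2] + 1}]")
        else:
            names.append(f"pi{tag[1] + 1}")
    pd.DataFrame(cov.cov, index=names, columns=names).to_csv(path)
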