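"""File formats: response matrices, draws, configs, provenance headers.

Response matrices are CSV with a header row of item IDs and 0/1 cells
(or 0..J_i in polytomous mode); NA cells are allowed only when a booklet
design file accompanies the data.  Draws are CSV (one row per retained
iteration) with a JSON sidecar holding seed/config provenance.  Every
file written here starts with ``#``-prefixed provenance comment lines.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .sampler import ChainConfig, GibbsDraws

__all__ = [
    "read_response_matrix",
    "write_response_matrix",
    "read_design",
    "write_draws",
    "read_draws",
    "provenance_header",
    "load_config",
]

NA_TOKENS = ("", "NA", "NaN", "nan")


def provenance_header(version: str, seed, config: dict | None = None) -> str:
    cfg = json.dumps(config or {}, sort_keys=True, default=str)
    digest = hashlib.sha256(cfg.encode()).hexdigest()[:12]
    return (f"# margrasch v{version}\n"
            f"# seed: {seed}\n"
            f"# config_sha256: {digest}\n")


def read_response_matrix(path, allow_na: bool = False,
                         max_category: int = 1) -> tuple[np.ndarray, list[str]]:
    """Read a person × item CSV; returns (matrix, item IDs).

    Cells must be integers in 0..max_category.  NA cells produce -1 in the
    returned matrix and are rejected unless ``allow_na`` (set when a design
    file maps rows to booklets).
    """
    df = pd.read_csv(path, comment="#", dtype=str)
    if df.shape[1] < 1:
        raise ValueError(f"{path}: no item columns found")
    items = [str(c) for c in df.columns]
    raw = df.to_numpy()
    out = np.full(raw.shape, -1, dtype=np.int64)
    for r in range(raw.shape[0]):
        for c_ in range(raw.shape[1]):
            cell = raw[r, c_]
            if cell is None or (isinstance(cell, float) and np.isnan(cell)) \
                    or str(cell).strip() in NA_TOKENS:
                if not allow_na:
                    raise ValueError(
                        f"{path}: missing value at row {r + 1}, column "
                        f"'{items[c_]}' but no design file was supplied")
                continue
            try:
                v = int(str(cell).strip())
            except ValueError:
                v = -99
            if not 0 <= v <= max_category:
                raise ValueError(
                    f"{path}: invalid symbol '{cell}' at row {r + 1}, column "
                    f"'{items[c_]}' (expected integers 0..{max_category})")
            out[r, c_] = v
    return out, items


def write_response_matrix(path, X: np.ndarray, items: list[str],
                          version: str = "0", seed=None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(provenance_header(version, seed))
        df = pd.DataFrame(np.asarray(X), columns=items)
        df = df.astype(object).where(np.asarray(X) >= 0, "NA")
        df.to_csv(fh, index=False)


def read_design(path) -> dict[str, list[str]]:
    """Booklet design: JSON mapping booklet names to item-ID lists."""
    with open(path) as fh:
        design = json.load(fh)
    booklets = design.get("booklets", design)
    if not isinstance(booklets, dict) or not booklets:
        raise ValueError(f"{path}: expected a 'booklets' mapping")
    return {str(k): [str(i) for i in v] for k, v in booklets.items()}


def split_neat(X: np.ndarray, items: list[str],
               design: dict[str, list[str]]) -> tuple:
    """Partition rows of an NA-bearing matrix into two NEAT booklets.

    Returns (X_xy, X_xz, n_anchor, booklet column orders).  The anchor is
    the intersection of the two booklets' item lists; each row must be
    complete on exactly one booklet.
    """
    if len(design) != 2:
        raise ValueError("NEAT split expects exactly two booklets")
    (name1, items1), (name2, items2) = sorted(design.items())
    anchor = [i for i in items1 if i in items2]
    if not anchor:
        raise ValueError("booklets share no anchor items")
    uniq1 = [i for i in items1 if i not in anchor]
    uniq2 = [i for i in items2 if i not in anchor]
    col = {name: k for k, name in enumerate(items)}
    for missing in (set(anchor + uniq1 + uniq2) - set(items)):
        raise ValueError(f"design references unknown item '{missing}'")
    order1 = [col[i] for i in anchor + uniq1]
    order2 = [col[i] for i in anchor + uniq2]
    rows1, rows2 = [], []
    for r in range(X.shape[0]):
        ok1 = np.all(X[r, order1] >= 0)
        ok2 = np.all(X[r, order2] >= 0)
        if ok1 == ok2:
            raise ValueError(f"row {r + 1} matches {'both booklets' if ok1 else 'no booklet'}")
        (rows1 if ok1 else rows2).append(r)
    X_xy = X[np.array(rows1, dtype=int)][:, order1]
    X_xz = X[np.array(rows2, dtype=int)][:, order2]
    return X_xy, X_xz, len(anchor), (anchor + uniq1, anchor + uniq2)


def write_draws(draws: GibbsDraws, path, version: str = "0") -> None:
    """Draws as CSV (b_1..b_n, lambda_0..lambda_n) plus a JSON sidecar."""
    path = Path(path)
    n = draws.n_items
    cols = [f"b_{i + 1}" for i in range(n)] + [f"lambda_{s}" for s in range(n + 1)]
    cfg = draws.config.to_dict()
    with open(path, "w") as fh:
        fh.write(provenance_header(version, cfg.get("seed"), cfg))
        pd.DataFrame(np.hstack([draws.b, draws.lam]), columns=cols).to_csv(
            fh, index=False)
    sidecar = path.with_suffix(path.suffix + ".json")
    with open(sidecar, "w") as fh:
        json.dump({"version": version, "config": cfg,
                   "stats_digest": draws.stats_digest,
                   "n_draws": draws.n_draws, "n_items": n}, fh, indent=2)


def read_draws(path) -> GibbsDraws:
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    b_cols = [c for c in df.columns if c.startswith("b_")]
    l_cols = [c for c in df.columns if c.startswith("lambda_")]
    sidecar = path.with_suffix(path.suffix + ".json")
    cfg = ChainConfig()
    digest = ""
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = json.load(fh)
        cfg = ChainConfig(**meta["config"])
        digest = meta.get("stats_digest", "")
    return GibbsDraws(df[b_cols].to_numpy(), df[l_cols].to_numpy(), cfg,
                      stats_digest=digest)


def load_config(path) -> dict:
    """Run configuration from YAML or JSON."""
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        import yaml

        cfg = yaml.safe_load(text)
    else:
        cfg = json.loads(text)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg
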