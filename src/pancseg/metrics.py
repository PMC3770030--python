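"""Segmentation-overlap metrics: FPE, FNE and the similarity index.

Against a gold-standard mask G, an extracted region O is scored by

* false-positive error  ``FPE = N(O ∩ B) / N(G)`` with B the complement
  of G — extracted pixels outside the truth, normalized by truth size;
  can exceed 1 under gross oversegmentation (leakage);
* false-negative error  ``FNE = (N(G) - N(O ∩ G)) / N(G)`` — the missed
  fraction of the truth, in [0, 1];
* similarity index      ``SI = 2 N(O ∩ G) / (N(O) + N(G))`` — the Dice
  coefficient, in [0, 1].
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

__all__ = ["MetricsReport", "compute_metrics", "write_metrics_json", "append_metrics_csv"]


@dataclass(frozen=True)
class MetricsReport:
    """Overlap metrics plus the raw pixel counts they derive from."""

    fpe: float
    fne: float
    si: float
    n_o: int
    n_g: int
    n_og: int
    n_ob: int

    @property
    def fpe_percent(self) -> float:
        return 100.0 * self.fpe

    @property
    def fne_percent(self) -> float:
        return 100.0 * self.fne

    @property
    def si_percent(self) -> float:
        return 100.0 * self.si

    def as_dict(self) -> dict:
        d = asdict(self)
        d.update(
            fpe_percent=self.fpe_percent,
            fne_percent=self.fne_percent,
            si_percent=self.si_percent,
        )
        return d


def compute_metrics(o: np.ndarray, g: np.ndarray) -> MetricsReport:
    """Score an extracted mask ``o`` against a nonempty gold standard ``g``."""
    o = np.asarray(o, dtype=bool)
    g = np.asarray(g, dtype=bool)
    if o.shape != g.shape:
        raise ValueError(f"shape mismatch: extracted {o.shape} vs gold standard {g.shape}")
    n_g = int(g.sum())
    if n_g == 0:
        raise ValueError("gold standard is empty: FPE and FNE are undefined")
    n_o = int(o.sum())
    n_og = int((o & g).sum())
    n_ob = n_o - n_og
    fpe = n_ob / n_g
    fne = (n_g - n_og) / n_g
    si = 2.0 * n_og / (n_o + n_g) if (n_o + n_g) else 1.0
    return MetricsReport(fpe=fpe, fne=fne, si=si, n_o=n_o, n_g=n_g, n_og=n_og, n_ob=n_ob)


def write_metrics_json(report: MetricsReport, path) -> None:
    Path(path).write_text(json.dumps(report.as_dict(), indent=2) + "\n")


def append_metrics_csv(report: MetricsReport, path, slice_id: str = "") -> None:
    """Append one row (id, counts, fractional metrics); header on creation."""
    path = Path(path)
    new = not path.exists()
    with path.open("a", newline="") as fh:
        writer = csv.writer(fh)
        if new:
            writer.writerow(["id", "n_o", "n_g", "n_og", "fpe", "fne", "si"])
        writer.writerow(
            [slice_id, report.n_o, report.n_g, report.n_og, report.fpe, report.fne, report.si]
        )
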