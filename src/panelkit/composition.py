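"""Subspecies genome composition by constrained regression.

An individual's per-locus allele frequencies ``f_i = dosage / 2`` are
modelled as a convex combination of two reference-population frequency
vectors::

    f_i = f_P * b_P + f_W * (1 - b_P) + e,      0 <= b_P <= 1

where ``f_P`` and ``f_W`` are plains- and wood-reference alt-allele
frequencies and ``b_P`` (the *PlainsScore*, reported in percent) is the
genome proportion attributable to plains bison.  With a single bounded
coefficient the least-squares solution has a closed form: the unconstrained
estimate

    b_u = sum((f_i - f_W)(f_P - f_W)) / sum((f_P - f_W)^2)

clipped to [0, 1].  The general bounded-least-squares solver (scipy BVLS)
is retained for problems with more than two reference populations; for the
two-reference model the closed form is exact and is the default.

Reference frequencies are plug-in point estimates from the labelled
reference animals (no shrinkage).  Loci missing for an animal are dropped
for that animal only; loci where the two references coincide carry no
signal but are permitted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, SampleRecord


@dataclass
class ReferenceFrequencies:
    """Aligned reference alt-allele frequency vectors for the two subspecies.

    ``n_p`` / ``n_w`` record how many reference animals the estimates came
    from (0 for exact population frequencies, e.g. simulation truth)."""

    locus_ids: list[str]
    f_p: np.ndarray
    f_w: np.ndarray
    n_p: int = 0
    n_w: int = 0

    def __post_init__(self) -> None:
        self.f_p = np.asarray(self.f_p, dtype=float)
        self.f_w = np.asarray(self.f_w, dtype=float)
        m = len(self.locus_ids)
        if self.f_p.shape != (m,) or self.f_w.shape != (m,):
            raise ValueError("frequency vectors must align with locus_ids")
        for name, v in (("f_p", self.f_p), ("f_w", self.f_w)):
            if ((v < 0) | (v > 1)).any():
                raise ValueError(f"{name} outside [0, 1]")

    @property
    def m(self) -> int:
        return len(self.locus_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"locus_id": self.locus_ids, "f_P": self.f_p, "f_W": self.f_w}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, n_p: int = 0, n_w: int = 0):
        return cls(
            locus_ids=list(df["locus_id"]),
            f_p=df["f_P"].to_numpy(),
            f_w=df["f_W"].to_numpy(),
            n_p=n_p,
            n_w=n_w,
        )


@dataclass(frozen=True)
class CompositionEstimate:
    sample_id: str
    b_p: float
    residual_ss: float
    m_used: int

    @property
    def wood_proportion(self) -> float:
        return 1.0 - self.b_p

    @property
    def plains_score_percent(self) -> float:
        return 100.0 * self.b_p


def reference_freqs(
    gm: GenotypeMatrix,
    sample_metadata: Sequence[SampleRecord],
    min_confidence: int = 1,
) -> ReferenceFrequencies:
    """Estimate f_P / f_W from labelled reference animals.

    Animals labelled ``plains`` or ``wood`` with confidence level at or
    better than ``min_confidence`` (1 = absolutely confident) form the two
    reference populations.  Loci with zero calls in either group are dropped
    with a warning.
    """
    meta = {r.sample_id: r for r in sample_metadata}

    def group(label: str) -> list[str]:
        return [
            s
            for s in gm.sample_ids
            if s in meta
            and meta[s].subspecies_label == label
            and meta[s].confidence_level <= min_confidence
        ]

    plains, wood = group("plains"), group("wood")
    if not plains or not wood:
        raise ValueError(
            f"need >=1 plains and >=1 wood reference sample at confidence "
            f"<= {min_confidence}; got {len(plains)} / {len(wood)}"
        )

    def freqs(sample_ids: list[str]) -> np.ndarray:
        d = gm.subset(sample_ids=sample_ids).dosages
        called = d != MISSING
        n = called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, np.where(called, d, 0).sum(axis=0) / (2.0 * np.maximum(n, 1)), np.nan)

    f_p, f_w = freqs(plains), freqs(wood)
    ok = np.isfinite(f_p) & np.isfinite(f_w)
    if not ok.all():
        warnings.warn(
            f"dropping {int((~ok).sum())} loci with zero calls in a reference group",
            stacklevel=2,
        )
    return ReferenceFrequencies(
        locus_ids=[l for l, keep in zip(gm.locus_ids, ok) if keep],
        f_p=f_p[ok],
        f_w=f_w[ok],
        n_p=len(plains),
        n_w=len(wood),
    )


def _closed_form(y: np.ndarray, x: np.ndarray) -> float:
    den = float(x @ x)
    if den == 0.0:
        raise ValueError("references indistinguishable on provided loci")
    return float(np.clip((y @ x) / den, 0.0, 1.0))


def _bvls(y: np.ndarray, x: np.ndarray) -> float:
    from scipy.optimize import lsq_linear

    if float(x @ x) == 0.0:
        raise ValueError("references indistinguishable on provided loci")
    res = lsq_linear(x[:, None], y, bounds=(0.0, 1.0), method="bvls")
    return float(res.x[0])


def estimate_composition(
    dosages_for_sample: np.ndarray,
    ref: ReferenceFrequencies,
    sample_id: str = "",
    method: Literal["closed_form", "bvls"] = "closed_form",
) -> CompositionEstimate:
    """Estimate one animal's plains proportion ``b_P``.

    ``dosages_for_sample`` must be aligned to ``ref.locus_ids``; missing
    entries (:data:`~panelkit.genotype_io.MISSING`) are dropped for this
    animal.  ``method="bvls"`` routes through the general bounded
    least-squares solver instead of the exact closed form (the two agree to
    numerical precision; the closed form is the implementation theorem for
    the single-coefficient model).
    """
    d = np.asarray(dosages_for_sample)
    if d.shape != (ref.m,):
        raise ValueError(f"expected {ref.m} dosages, got shape {d.shape}")
    called = d != MISSING
    if not called.any():
        raise ValueError(f"{sample_id or 'sample'}: no non-missing loci")
    f_i = d[called] / 2.0
    x = (ref.f_p - ref.f_w)[called]
    y = f_i - ref.f_w[called]
    b = _closed_form(y, x) if method == "closed_form" else _bvls(y, x)
    resid = y - b * x
    return CompositionEstimate(
        sample_id=sample_id,
        b_p=b,
        residual_ss=float(resid @ resid),
        m_used=int(called.sum()),
    )


def estimate_composition_matrix(
    gm: GenotypeMatrix, ref: ReferenceFrequencies
) -> list[CompositionEstimate]:
    """Vectorised closed-form estimation for every sample in ``gm``.

    ``gm`` is subset/reordered to ``ref.locus_ids`` first, so panels and
    genotype files need not be pre-aligned.
    """
    sub = gm.subset(locus_ids=ref.locus_ids)
    D = sub.dosages.astype(float)
    W = sub.dosages != MISSING
    x = ref.f_p - ref.f_w
    Y = np.where(W, D / 2.0 - ref.f_w, 0.0)
    num = Y @ x
    den = W @ (x * x)
    if (den == 0.0).any():
        bad = [sub.sample_ids[i] for i in np.where(den == 0.0)[0][:5]]
        raise ValueError(f"references indistinguishable on called loci for {bad}")
    b = np.clip(num / den, 0.0, 1.0)
    resid = Y - b[:, None] * np.where(W, x, 0.0)
    rss = (resid * resid).sum(axis=1)
    m_used = W.sum(axis=1)
    return [
        CompositionEstimate(sid, float(b[i]), float(rss[i]), int(m_used[i]))
        for i, sid in enumerate(sub.sample_ids)
    ]


def composition_summary(
    estimates: Sequence[CompositionEstimate],
    population_labels: Sequence[str],
) -> pd.DataFrame:
    """Median/mean/SD of PlainsScore (%) per labelled population."""
    if len(estimates) != len(population_labels):
        raise ValueError("one population label per estimate required")
    df = pd.DataFrame(
        {
            "population": list(population_labels),
            "plains_score": [e.plains_score_percent for e in estimates],
        }
    )
    out = (
        df.groupby("population", sort=False)["plains_score"]
        .agg(n="size", median="median", mean="mean", sd="std")
        .reset_index()
    )
    out["sd"] = out["sd"].fillna(0.0)
    return out
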