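"""Proteolytic-activity arithmetic for the modified Anson assay.

The assay digests a haemoglobin substrate, precipitates undigested protein,
develops the soluble fragments with Folin-phenol reagent and reads the
absorbance at 660 nm.  With OD_blank the ligand-free control:

    inhibition rate (%) = (OD_blank - OD_sample) / OD_blank * 100
    relative activity   =  OD_sample / OD_blank          (blank == 1)

A negative inhibition rate (relative activity above 1) is reported as-is:
it means the ligand *enhances* the enzyme's activity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

__all__ = ["ActivityTable", "inhibition_rate", "relative_activity"]


@dataclass(frozen=True)
class ActivityTable:
    """OD660 readings per ligand concentration plus the blank.

    ``samples`` is a list of (ligand concentration mol/L, OD660); replicate
    readings for the same concentration should be averaged before
    construction (see :func:`from_replicates`).
    """

    od_blank: float
    samples: tuple  # ((conc, od), ...)
    wavelength: float = 660.0  # nm
    sample_sd: tuple = ()  # optional per-sample SD from replicate averaging

    def __post_init__(self):
        if not (self.od_blank > 0):
            raise ValidationError("blank absorbance must be positive")
        for conc, od in self.samples:
            if conc < 0:
                raise ValidationError("ligand concentrations must be non-negative")
            if od < 0:
                raise ValidationError("absorbances must be non-negative")

    @classmethod
    def from_replicates(cls, rows, wavelength: float = 660.0) -> "ActivityTable":
        """Average replicate (conc, od) rows; conc == 0 defines the blank.

        The per-concentration standard deviation of the replicates is kept
        in ``sample_sd`` for reporting.
        """
        by_conc: dict[float, list[float]] = {}
        for conc, od in rows:
            by_conc.setdefault(float(conc), []).append(float(od))
        if 0.0 not in by_conc:
            raise ValidationError("no blank row (ligand concentration 0) found")
        blank = float(np.mean(by_conc.pop(0.0)))
        concs = sorted(by_conc)
        samples = tuple((c, float(np.mean(by_conc[c]))) for c in concs)
        sds = tuple(float(np.std(by_conc[c], ddof=0)) for c in concs)
        return cls(od_blank=blank, samples=samples, wavelength=wavelength,
                   sample_sd=sds)


def inhibition_rate(table: ActivityTable) -> list[tuple[float, float]]:
    """Per-sample inhibition in percent; negative values mean activation."""
    return [
        (conc, (table.od_blank - od) / table.od_blank * 100.0)
        for conc, od in table.samples
    ]


def relative_activity(table: ActivityTable) -> list[tuple[float, float]]:
    """Per-sample activity relative to the blank (blank normalised to 1)."""
    return [(conc, od / table.od_blank) for conc, od in table.samples]
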