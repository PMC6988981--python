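"""Bundled reference data and validation-pair table I/O.

The packaged table ``cnv_penetrance_validation.csv`` pairs published penetrance
estimates for 21 schizophrenia-associated CNVs, compiled from two case-control
compendia (Vassos et al. 2009; Rosenfeld et al. 2011, rows 9-21), with the
values the original web calculator produced from the same inputs. Values are
kept exactly as printed in the source tables, including two rows whose
published lower bound carries an apparent transcription slip (0.79 printed for
0.079, which would invert the interval); the loader repairs such rows by
default, see :func:`load_validation_pairs`.
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path
from typing import Sequence

import pandas as pd

from .core import PenetranceEstimate
from .errors import TableParseError
from .validation import ValidationPair

__all__ = ["bundled_cnv_table_path", "load_validation_pairs"]

logger = logging.getLogger(__name__)

PAIR_COLUMNS = (
    "variant_id",
    "pub_median",
    "pub_lower",
    "pub_upper",
    "calc_median",
    "calc_lower",
    "calc_upper",
)


def bundled_cnv_table_path() -> Path:
    """Filesystem path of the packaged 21-CNV validation-pair table."""
    return Path(resources.files("penbayes").joinpath("data/cnv_penetrance_validation.csv"))


def _repair_misordered(label: str, median: float, lower: float, upper: float) -> float:
    """Shift a mis-ordered lower bound's decimal point if that restores ordering."""
    if lower <= upper:
        return lower
    shifted = lower / 10.0
    if shifted <= median <= upper:
        logger.warning(
            "%s: published lower bound %.3g exceeds upper bound %.3g; "
            "reading it as %.3g (decimal-point transcription slip)",
            label,
            lower,
            upper,
            shifted,
        )
        return shifted
    raise TableParseError(
        f"{label}: interval ({lower}, {upper}) is mis-ordered and not repairable "
        "by a decimal shift"
    )


def load_validation_pairs(
    source: str | Path | None = None,
    repair_typos: bool = True,
) -> list[ValidationPair]:
    """Read a validation-pair CSV into :class:`ValidationPair` objects.

    Parameters
    ----------
    source
        CSV with columns ``variant_id, pub_median, pub_lower, pub_upper,
        calc_median, calc_lower, calc_upper``. Defaults to the bundled
        21-CNV table.
    repair_typos
        If True (default), a row whose lower bound exceeds its upper bound is
        repaired by shifting the lower bound's decimal point one place when
        that restores lower <= median <= upper, with a logged warning.
        If False, such rows raise :class:`TableParseError`.
    """
    path = bundled_cnv_table_path() if source is None else Path(source)
    df = pd.read_csv(path)
    missing = set(PAIR_COLUMNS) - set(df.columns)
    if missing:
        raise TableParseError(f"missing required columns: {sorted(missing)}")

    pairs: list[ValidationPair] = []
    for idx, row in df.iterrows():
        line = int(idx) + 2  # header is line 1
        label = str(row["variant_id"])
        try:
            pub_lower = float(row["pub_lower"])
            calc_lower = float(row["calc_lower"])
            if repair_typos:
                pub_lower = _repair_misordered(
                    label, float(row["pub_median"]), pub_lower, float(row["pub_upper"])
                )
                calc_lower = _repair_misordered(
                    label, float(row["calc_median"]), calc_lower, float(row["calc_upper"])
                )
            pairs.append(
                ValidationPair(
                    variant_label=label,
                    published=PenetranceEstimate(
                        median=float(row["pub_median"]),
                        ci_lower=pub_lower,
                        ci_upper=float(row["pub_upper"]),
                    ),
                    recomputed=PenetranceEstimate(
                        median=float(row["calc_median"]),
                        ci_lower=calc_lower,
                        ci_upper=float(row["calc_upper"]),
                    ),
                )
            )
        except TableParseError:
            raise
        except ValueError as exc:
            raise TableParseError(str(exc), line=line) from exc
    return pairs
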