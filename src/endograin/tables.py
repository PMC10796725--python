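"""Packaged per-variety report tables and their loaders.

``table3.csv`` carries the 25-variety GI panel (morphology, biochemistry
and in-vivo GI of the Italian genotypes); ``table4.csv`` the 29 further
varieties characterised by FESEM only (11 Italian + 18 IRRI accessions).
Cells are transcribed as printed, blanks where the segmentation algorithm
could not process the compact endosperm.  The censored amylose entry
("< 5", the waxy variety) is handled by an explicit policy, never silently.
"""

from __future__ import annotations

import hashlib
from importlib import resources
from typing import Literal

import pandas as pd

__all__ = [
    "load_table3",
    "load_table4",
    "verify_fixture_checksums",
    "FixtureChecksumError",
    "FIXTURE_SHA256",
]

# sha256 of the packaged CSV bytes; reproduction aborts on mismatch
FIXTURE_SHA256 = {
    "table3.csv": "ba8b3667558edf32e62d03edbde408063ff5531043db776891b050661fa06f38",
    "table4.csv": "e2a5f918205c8527f68f05ea30e657939f7f8da2198ab6c36d806c5ededf6ad1",
}

CensorPolicy = Literal["impute2.5", "impute0", "impute5", "exclude"]


class FixtureChecksumError(RuntimeError):
    """A packaged fixture does not match its recorded checksum."""


def _read_fixture(name: str) -> bytes:
    return resources.files("endograin.data").joinpath(name).read_bytes()


def verify_fixture_checksums() -> None:
    """Abort (raise) if any packaged table differs from its recorded hash."""
    for name, expected in FIXTURE_SHA256.items():
        got = hashlib.sha256(_read_fixture(name)).hexdigest()
        if got != expected:
            raise FixtureChecksumError(f"{name}: sha256 {got} != recorded {expected}")


def load_table3(censored_amylose: CensorPolicy = "impute2.5") -> pd.DataFrame:
    """The GI panel, indexed by variety.

    ``censored_amylose`` says what to do with the "< 5" amylose cell of
    the waxy variety: impute 2.5 (the interval midpoint, default), 0, 5,
    or exclude (NaN).
    """
    import io

    df = pd.read_csv(io.BytesIO(_read_fixture("table3.csv")), index_col="variety")
    amylose = df["amylose_pct"].copy()
    censored = amylose.astype(str).str.strip().str.startswith("<")
    replacement = {"impute2.5": 2.5, "impute0": 0.0, "impute5": 5.0, "exclude": float("nan")}
    if censored_amylose not in replacement:
        raise ValueError(f"unknown censored-amylose policy {censored_amylose!r}")
    amylose[censored] = replacement[censored_amylose]
    df["amylose_pct"] = pd.to_numeric(amylose)
    df["amylose_censored"] = censored
    return df


def load_table4() -> pd.DataFrame:
    """The FESEM-only panel (Italian + IRRI varieties), indexed by variety."""
    import io

    return pd.read_csv(io.BytesIO(_read_fixture("table4.csv")), index_col="variety")
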