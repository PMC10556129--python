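"""Domain types for pottery lipid-residue records and food-source references.

The vocabulary follows compound-specific stable isotope analysis of
archaeological pottery: per-sherd lipid yields, compound abundances
(biomarkers), and δ13C values of the three fatty-acid proxies (palmitic
C16:0, stearic C18:0, oleic C18:1) expressed in ‰ relative to VPDB.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Fatty acids carrying δ13C proxies, in canonical order.
PROXIES: tuple[str, ...] = ("C16:0", "C18:0", "C18:1")

ALKANOLS: tuple[str, ...] = tuple(f"alkanol_C{n}" for n in range(24, 38, 2))
HOPANES: tuple[str, ...] = tuple(f"hopane_C{n}" for n in range(30, 34))

#: The closed vocabulary of compound identifiers accepted in abundance tables.
COMPOUND_KEYS: tuple[str, ...] = (
    "C12:0",
    "C16:0",
    "C18:0",
    "C18:1",
    "TMTD",
    "pristanic",
    "phytanic_SRR",
    "phytanic_RRR",
    "APAA_C16",
    "APAA_C18",
    "APAA_C20",
    "DHA",
    *ALKANOLS,
    *HOPANES,
    "levoglucosan",
    "sterol",
    "terpene",
)

TRADITIONS: tuple[str, ...] = ("Taquara-Itararé", "Guarani")
DECORATIONS: tuple[str, ...] = ("plain", "decorated", "unknown")

#: Sanity window for δ13C of fatty acids (‰ VPDB); values outside indicate
#: unit errors (e.g. per cent instead of per mille).
D13C_WINDOW: tuple[float, float] = (-45.0, 0.0)

DEFAULT_SOURCES: tuple[str, ...] = ("maize", "marine", "C3_plant", "ruminant")


class ValidationError(ValueError):
    """Raised when a record or table violates a domain invariant."""


def _check_compound(key: str) -> str:
    if key not in COMPOUND_KEYS:
        raise ValidationError(f"unknown compound identifier: {key!r}")
    return key


@dataclass
class SherdRecord:
    """One pottery sample: lipid yield, compound abundances, δ13C proxies.

    ``abundances`` maps compound identifiers to non-negative relative
    abundances; an absent key means the compound was not detected or not
    measured — absence is never conflated with zero downstream.
    ``d13c`` maps a proxy fatty acid to ``(value ‰, analytical sd ‰)``.
    """

    sample_id: str
    site: str
    tradition: str
    decoration: str = "unknown"
    lipid_yield: float = 0.0
    abundances: dict[str, float] = field(default_factory=dict)
    d13c: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.tradition not in TRADITIONS:
            raise ValidationError(
                f"sample {self.sample_id!r}: unknown tradition {self.tradition!r}"
            )
        if self.decoration not in DECORATIONS:
            raise ValidationError(
                f"sample {self.sample_id!r}: unknown decoration {self.decoration!r}"
            )
        if not np.isfinite(self.lipid_yield) or self.lipid_yield < 0:
            raise ValidationError(
                f"sample {self.sample_id!r}: lipid_yield must be >= 0, "
                f"got {self.lipid_yield}"
            )
        for key, value in self.abundances.items():
            _check_compound(key)
            if not np.isfinite(value) or value < 0:
                raise ValidationError(
                    f"sample {self.sample_id!r}: abundance of {key} must be "
                    f"non-negative, got {value}"
                )
        lo, hi = D13C_WINDOW
        for proxy, (value, sd) in self.d13c.items():
            if proxy not in PROXIES:
                raise ValidationError(
                    f"sample {self.sample_id!r}: δ13C proxy must be one of "
                    f"{PROXIES}, got {proxy!r}"
                )
            if not (lo <= value <= hi):
                raise ValidationError(
                    f"sample {self.sample_id!r}: δ13C {proxy} = {value} ‰ outside "
                    f"the sanity window [{lo}, {hi}]"
                )
            if not (np.isfinite(sd) and sd > 0):
                raise ValidationError(
                    f"sample {self.sample_id!r}: δ13C {proxy} sd must be > 0, got {sd}"
                )

    def proxy_value(self, proxy: str) -> float | None:
        """δ13C value for ``proxy`` or None when not measured."""
        entry = self.d13c.get(proxy)
        return None if entry is None else entry[0]


@dataclass
class SourceReference:
    """Fatty-acid isotope signature of one food source.

    ``delta_mean``/``delta_sd`` give the δ13C signature (‰ VPDB) of each
    proxy fatty acid; ``conc_pct`` the concentration of that fatty acid as
    % of total fatty acids in the source; ``fa_per_dry_weight`` the total
    fatty-acid mass fraction per unit dry tissue (used to convert
    fatty-acid-basis contributions to a weight basis). ``signature_cov``
    optionally replaces the diagonal sds with a full 3x3 covariance over
    (δ16:0, δ18:0, δ18:1).
    """

    source_name: str
    delta_mean: dict[str, float]
    delta_sd: dict[str, float]
    conc_pct: dict[str, float]
    fa_per_dry_weight: float = 1.0
    signature_cov: np.ndarray | None = None

    def __post_init__(self) -> None:
        for mapping, label in (
            (self.delta_mean, "delta_mean"),
            (self.delta_sd, "delta_sd"),
            (self.conc_pct, "conc_pct"),
        ):
            missing = [p for p in PROXIES if p not in mapping]
            if missing:
                raise ValidationError(
                    f"source {self.source_name!r}: {label} missing {missing}"
                )
        for proxy in PROXIES:
            if self.delta_sd[proxy] <= 0:
                raise ValidationError(
                    f"source {self.source_name!r}: delta_sd[{proxy}] must be > 0"
                )
            if self.conc_pct[proxy] < 0:
                raise ValidationError(
                    f"source {self.source_name!r}: conc_pct[{proxy}] must be >= 0"
                )
        total = sum(self.conc_pct[p] for p in PROXIES)
        if total > 100 + 1e-9:
            raise ValidationError(
                f"source {self.source_name!r}: proxy concentrations sum to "
                f"{total:.3f} % > 100 % of total fatty acids"
            )
        if not (np.isfinite(self.fa_per_dry_weight) and self.fa_per_dry_weight > 0):
            raise ValidationError(
                f"source {self.source_name!r}: fa_per_dry_weight must be > 0"
            )
        if self.signature_cov is not None:
            cov = np.asarray(self.signature_cov, dtype=float)
            if cov.shape != (3, 3):
                raise ValidationError(
                    f"source {self.source_name!r}: signature_cov must be 3x3"
                )
            if not np.allclose(cov, cov.T, atol=1e-10):
                raise ValidationError(
                    f"source {self.source_name!r}: signature_cov not symmetric"
                )
            if np.min(np.linalg.eigvalsh(cov)) < -1e-10:
                raise ValidationError(
                    f"source {self.source_name!r}: signature_cov not positive "
                    "semi-definite"
                )
            self.signature_cov = cov
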