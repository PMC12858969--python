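"""Pipeline configuration: every threshold the cascade, classifier and
transcript flagging use, with the study defaults.

Defaults encode the published analysis settings: gnomAD minor allele
frequency <= 1e-4 with total allele count <= 5 (and <= 5 in an in-house
database), CADD PHRED >= 15 for missense, SpliceAI >= 0.5 for splice-site
variants, REVEL >= 0.75 / <= 0.25 for the PP3/BP4 computational criteria,
population frequency < 0.01% for PM2 at supporting strength, and the
five-class point bands (pathogenic >= 10, likely pathogenic 6..9, VUS
-1..5, likely benign -6..-2, benign <= -7).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path

from .errors import ConfigurationError
from .models import CONSEQUENCE_VOCABULARY, DEFAULT_KEPT_CONSEQUENCES

_FRACTION_FIELDS = (
    "maf_max",
    "spliceai_min",
    "revel_pathogenic_min",
    "revel_benign_max",
    "pm2_af_max",
    "padj_threshold",
)


@dataclass(slots=True)
class PipelineConfig:
    # --- filter cascade ---
    maf_max: float = 1e-4
    gnomad_ac_max: int = 5
    inhouse_ac_max: int = 5
    kept_consequences: frozenset[str] = field(default=DEFAULT_KEPT_CONSEQUENCES)
    promoter_whitelist_genes: frozenset[str] = field(default=frozenset({"BMPR2"}))
    cadd_min_missense: float = 15.0
    spliceai_min: float = 0.5
    #: Optional quality pre-gate applied before the frequency stage.
    qual_min: float | None = None
    require_filter_pass: bool = False
    # --- ACMG criteria ---
    revel_pathogenic_min: float = 0.75
    revel_benign_max: float = 0.25
    pm2_af_max: float = 1e-4  # "< 0.01%", strict inequality
    # --- five-class point bands (lower bound of each class) ---
    pathogenic_min: int = 10
    likely_pathogenic_min: int = 6
    vus_min: int = -1
    likely_benign_min: int = -6
    # --- transcript flagging ---
    lfc_threshold: float = 1.0
    padj_threshold: float = 0.05
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        for name in _FRACTION_FIELDS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v!r}")
        for name in ("gnomad_ac_max", "inhouse_ac_max"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        unknown = set(self.kept_consequences) - CONSEQUENCE_VOCABULARY
        if unknown:
            raise ConfigurationError(f"kept_consequences contains unknown terms: {sorted(unknown)}")
        if not (
            self.pathogenic_min > self.likely_pathogenic_min > self.vus_min > self.likely_benign_min
        ):
            raise ConfigurationError(
                "class band bounds must be strictly decreasing "
                "(pathogenic_min > likely_pathogenic_min > vus_min > likely_benign_min)"
            )
        if self.pseudocount <= 0:
            raise ConfigurationError("pseudocount must be positive")

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        """Return a copy with the given fields replaced (validated anew)."""
        valid = {f.name for f in fields(self)}
        unknown = set(kwargs) - valid
        if unknown:
            raise ConfigurationError(f"unknown configuration keys: {sorted(unknown)}")
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, frozenset):
                v = sorted(v)
            out[f.name] = v
        return out


_SET_FIELDS = {"kept_consequences", "promoter_whitelist_genes"}
_INT_FIELDS = {
    "gnomad_ac_max",
    "inhouse_ac_max",
    "pathogenic_min",
    "likely_pathogenic_min",
    "vus_min",
    "likely_benign_min",
}
_BOOL_FIELDS = {"require_filter_pass"}


def load_config(path: str | Path) -> PipelineConfig:
    """Read a flat ``key = value`` file into a :class:`PipelineConfig`.

    Blank lines and ``#`` comments are ignored. Set-valued keys take a
    comma-separated list; ``qual_min`` accepts ``none``.
    """
    overrides: dict = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigurationError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        if key in _SET_FIELDS:
            overrides[key] = frozenset(v.strip() for v in value.split(",") if v.strip())
        elif key in _INT_FIELDS:
            overrides[key] = int(value)
        elif key in _BOOL_FIELDS:
            overrides[key] = value.lower() in ("1", "true", "yes")
        elif key == "qual_min":
            overrides[key] = None if value.lower() in ("none", "") else float(value)
        else:
            overrides[key] = float(value)
    return PipelineConfig().with_overrides(**overrides)
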