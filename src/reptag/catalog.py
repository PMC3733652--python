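"""Machine-readable catalog of tagged-REP family consensi.

A family couples a 4 bp terminal tag (canonical GTAG or CGTC plus an
explicit list of accepted degenerate variants) to a stem-loop geometry:
a left-arm consensus in the NC-IUB degenerate alphabet (the right arm is
its reverse complement), a loop length range with optional fixed
consensus or terminal-motif classes, optional unpaired extra bases
between tag and stem, and an optional 3 bp tail at the untagged end.
Species-specific overrides (e.g. shorter stems in one isolate) ride
along as named variants.

The default catalog packaged with this module holds 24 GTAG and 4 CGTC
families whose geometries follow the published text descriptions; arm
consensi for families whose full alignment is published only graphically
are representative stand-ins and flagged ``arm_source: representative``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

from . import seqcore
from .seqcore import ALPHABET, reverse_complement

logger = logging.getLogger(__name__)

#: Super-family level geometry bounds (stem bp, loop bp).
GEOMETRY_BOUNDS = {
    "GTAG": {"arm": (5, 13), "loop": (2, 20)},
    "CGTC": {"arm": (8, 9), "loop": (4, 5)},
}

_KNOWN_KEYS = {
    "family", "super_family", "tag", "tag_alternatives", "tag_end",
    "extra_bases", "arms", "arm_source", "loop_range", "loop_consensus",
    "loop_classes", "long_loop", "tail", "species_variant",
}


class CatalogError(ValueError):
    """Malformed catalog file or invariant violation."""


@dataclass(frozen=True)
class FamilyDefinition:
    """One tagged-REP family consensus.

    ``arms`` lists left-arm consensus variants (families with alternative
    stems, or stems of two lengths, carry several). ``loop_classes`` are
    (left-motif, right-motif) terminal pairs for families whose loops vary
    in length but keep conserved GC-rich termini.
    """

    family_id: str
    super_family: str
    tag: str
    tag_alternatives: tuple[str, ...] = ()
    tag_end: str = "five_prime"
    extra_bases: str | None = None
    arms: tuple[str, ...] = ()
    arm_source: str = "representative"
    loop_range: tuple[int, int] = (2, 3)
    loop_consensus: str | None = None
    loop_classes: tuple[tuple[str, str], ...] = ()
    long_loop: bool = False
    tail: str | None = None
    species_variants: dict = field(default_factory=dict)

    @property
    def all_tags(self) -> tuple[str, ...]:
        return (self.tag,) + self.tag_alternatives

    @property
    def partial(self) -> bool:
        """True when only tag + geometry are known (no arm consensus)."""
        return not self.arms

    def tag_matches(self, four_mer: str) -> bool:
        """Does a concrete 4-mer fit the canonical tag or a listed variant?"""
        return any(
            seqcore.match_consensus(four_mer, t) == 0 for t in self.all_tags
        )

    def variant(self, name: str) -> "FamilyDefinition":
        """The family definition with a named species override applied."""
        return replace(self, **self.species_variants[name])


def _parse_loop_range(text: str, line_no: int) -> tuple[int, int]:
    try:
        lo, hi = (int(x) for x in text.split("-"))
    except ValueError as exc:
        raise CatalogError(f"line {line_no}: bad loop_range {text!r}") from exc
    if lo < 0 or hi < lo:
        raise CatalogError(f"line {line_no}: bad loop_range {text!r}")
    return lo, hi


def _check_seq(text: str, line_no: int, what: str) -> str:
    up = text.upper()
    if not up or set(up) - ALPHABET:
        raise CatalogError(f"line {line_no}: invalid {what} {text!r}")
    return up


def _build_definition(rec: dict[str, tuple[str, int]],
                      variants: list[tuple[str, dict, int]]) -> FamilyDefinition:
    def get(key, default=None):
        return rec[key][0] if key in rec else default

    def line_of(key):
        return rec[key][1]

    fam = get("family")
    if fam is None:
        any_line = next(iter(rec.values()))[1]
        raise CatalogError(f"line {any_line}: record without 'family' key")
    sup = get("super_family", "")
    if sup not in GEOMETRY_BOUNDS:
        raise CatalogError(
            f"family {fam}: unknown super_family {sup!r}"
        )
    tag = _check_seq(get("tag", ""), line_of("tag") if "tag" in rec else 0,
                     "tag")
    alts = tuple(
        _check_seq(t, line_of("tag_alternatives"), "tag alternative")
        for t in get("tag_alternatives", "").split()
    )
    tag_end = get("tag_end", "five_prime")
    if tag_end not in ("five_prime", "three_prime"):
        raise CatalogError(f"family {fam}: bad tag_end {tag_end!r}")
    arms = tuple(
        _check_seq(a, line_of("arms"), "arm") for a in get("arms", "").split()
    )
    loop_range = _parse_loop_range(get("loop_range", "2-3"),
                                   line_of("loop_range") if "loop_range" in rec
                                   else 0)
    loop_cons = get("loop_consensus")
    if loop_cons is not None:
        loop_cons = _check_seq(loop_cons, line_of("loop_consensus"),
                               "loop consensus")
    classes = []
    for pair in get("loop_classes", "").split():
        try:
            left, right = pair.split("/")
        except ValueError:
            raise CatalogError(
                f"family {fam}: bad loop class {pair!r}"
            ) from None
        classes.append((left.upper(), right.upper()))
    extra = get("extra_bases")
    if extra is not None:
        extra = _check_seq(extra, line_of("extra_bases"), "extra_bases")
    tail = get("tail")
    if tail is not None:
        tail = _check_seq(tail, line_of("tail"), "tail")
    sv: dict[str, dict] = {}
    for name, overrides, line_no in variants:
        parsed: dict = {}
        for key, value in overrides.items():
            if key == "arms":
                parsed["arms"] = tuple(
                    _check_seq(a, line_no, "variant arm")
                    for a in value.split(",")
                )
            elif key == "loop_range":
                parsed["loop_range"] = _parse_loop_range(value, line_no)
            elif key == "tail":
                parsed["tail"] = _check_seq(value, line_no, "variant tail")
            else:
                raise CatalogError(
                    f"line {line_no}: unknown variant override {key!r}"
                )
        sv[name] = parsed
    return FamilyDefinition(
        family_id=fam,
        super_family=sup,
        tag=tag,
        tag_alternatives=alts,
        tag_end=tag_end,
        extra_bases=extra,
        arms=arms,
        arm_source=get("arm_source", "representative"),
        loop_range=loop_range,
        loop_consensus=loop_cons,
        loop_classes=tuple(classes),
        long_loop=get("long_loop", "false").lower() == "true",
        tail=tail,
        species_variants=sv,
    )


def validate_definition(defn: FamilyDefinition) -> None:
    """Raise :class:`CatalogError` on any invariant violation."""
    bounds = GEOMETRY_BOUNDS[defn.super_family]
    for t in defn.all_tags:
        if len(t) != 4:
            raise CatalogError(
                f"family {defn.family_id}: tag {t!r} is not 4 bp"
            )
    arm_lo, arm_hi = bounds["arm"]
    for arm in defn.arms:
        if not arm_lo <= len(arm) <= arm_hi:
            raise CatalogError(
                f"family {defn.family_id}: arm {arm!r} length {len(arm)} "
                f"outside {arm_lo}-{arm_hi} bp"
            )
    loop_lo, loop_hi = bounds["loop"]
    lo, hi = defn.loop_range
    if lo < loop_lo or (hi > loop_hi and not defn.long_loop):
        raise CatalogError(
            f"family {defn.family_id}: loop range {lo}-{hi} outside "
            f"{loop_lo}-{loop_hi} bp and not flagged long_loop"
        )
    if defn.loop_consensus is not None:
        if not lo <= len(defn.loop_consensus) <= hi:
            raise CatalogError(
                f"family {defn.family_id}: loop consensus length outside "
                f"loop range"
            )
    for name, overrides in defn.species_variants.items():
        for arm in overrides.get("arms", ()):
            if len(arm) < 2 or len(arm) > arm_hi:
                raise CatalogError(
                    f"family {defn.family_id} variant {name}: "
                    f"implausible arm {arm!r}"
                )


def parse_catalog(text: str, source: str = "<string>") -> list[FamilyDefinition]:
    """Parse catalog text into validated family definitions."""
    records: list[FamilyDefinition] = []
    rec: dict[str, tuple[str, int]] = {}
    variants: list[tuple[str, dict, int]] = []

    def flush():
        nonlocal rec, variants
        if rec or variants:
            records.append(_build_definition(rec, variants))
        rec, variants = {}, []

    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            flush()
            continue
        if line.startswith("#"):
            continue
        if ":" not in line:
            raise CatalogError(f"line {line_no}: expected 'key: value'")
        key, _, value = line.partition(":")
        key = key.strip()
        value = value.strip()
        if key not in _KNOWN_KEYS:
            raise CatalogError(f"line {line_no}: unknown key {key!r}")
        if key == "species_variant":
            parts = value.split()
            if not parts:
                raise CatalogError(f"line {line_no}: empty species_variant")
            name, overrides = parts[0], {}
            for token in parts[1:]:
                if "=" not in token:
                    raise CatalogError(
                        f"line {line_no}: bad variant token {token!r}"
                    )
                k, _, v = token.partition("=")
                overrides[k] = v
            variants.append((name, overrides, line_no))
        else:
            if key in rec:
                raise CatalogError(
                    f"line {line_no}: duplicate key {key!r} in record"
                )
            rec[key] = (value, line_no)
    flush()

    seen: set[str] = set()
    for defn in records:
        if defn.family_id in seen:
            raise CatalogError(f"duplicate family id {defn.family_id}")
        seen.add(defn.family_id)
        validate_definition(defn)
    if not records:
        logger.warning("catalog %s contains no family definitions", source)
        warnings.warn(f"catalog {source} contains no family definitions",
                      stacklevel=2)
    return records


def load_catalog(path: str | Path | None = None) -> list[FamilyDefinition]:
    """Load family definitions from ``path`` (default: packaged catalog)."""
    if path is None:
        text = (
            resources.files("reptag").joinpath("data/families.txt")
            .read_text()
        )
        return parse_catalog(text, source="packaged default")
    p = Path(path)
    return parse_catalog(p.read_text(), source=str(p))


def family_geometry(
    defn: FamilyDefinition, species: str | None = None
) -> tuple[tuple[int, ...], tuple[int, int], str]:
    """Stem/loop geometry of a family: (arm lengths, loop range, tag end).

    ``species`` applies a named species variant before measuring, so e.g.
    short-stemmed isolates report their own arm length.
    """
    if species is not None:
        defn = defn.variant(species)
    arm_lens = tuple(sorted({len(a) for a in defn.arms}))
    return arm_lens, defn.loop_range, defn.tag_end


def element_length(defn: FamilyDefinition, arm_len: int, loop_len: int) -> int:
    """Total element span for a given arm/loop geometry."""
    return (
        len(defn.tag)
        + (len(defn.extra_bases) if defn.extra_bases else 0)
        + 2 * arm_len
        + loop_len
        + (len(defn.tail) if defn.tail else 0)
    )


def check_arm_consistency(defn: FamilyDefinition) -> bool:
    """Right arm implied by reverse complement: self-consistency check.

    With the right arm stored implicitly this reduces to verifying that
    reverse-complementing the left arm twice restores it, i.e. that the
    arm consensus survives the degenerate complement round trip.
    """
    return all(
        reverse_complement(reverse_complement(a)) == a for a in defn.arms
    )


def load_target_palindromes(path: str | Path | None = None) -> dict[str, str]:
    """Printed target-palindrome consensi keyed by host/family label."""
    if path is None:
        text = (
            resources.files("reptag")
            .joinpath("data/target_palindromes.txt")
            .read_text()
        )
    else:
        text = Path(path).read_text()
    out: dict[str, str] = {}
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition(":")
        out[key.strip()] = value.strip()
    return out
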