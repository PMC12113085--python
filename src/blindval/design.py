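"""Blinded presentation schedules with covert duplicate injection.

The review experiment works like this: every image has been segmented by
several sources (human annotators and/or a model).  All masks are pooled,
a random subset per source is covertly included a second time (to measure
the validator's self-consistency), the pool is shuffled into a single
uniformly random order, and each item gets an opaque random presentation
id.  The mapping presentation id → (image, source, replicate) is sealed
into a separate provenance file that the review interface never sees;
it is unsealed only at analysis time.
"""

from __future__ import annotations

import hashlib
import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import BlindingError, CatalogError, ProvenanceError, ScheduleError

__all__ = [
    "AnnotationCatalog",
    "PresentationItem",
    "SchedulePlan",
    "ProvenanceRecord",
    "read_manifest",
    "write_manifest",
    "build_schedule",
    "order_ranks",
    "seal",
    "unseal",
    "write_plan",
    "read_plan",
    "audit_blinded_bundle",
    "export_blinded_bundle",
]

# (image_id, source_id, replicate) with replicate in {1, 2}
Triple = tuple[str, str, int]


@dataclass(frozen=True)
class AnnotationCatalog:
    """A complete grid of masks: every (image, source) pair has exactly one.

    ``masks`` maps (image_id, source_id) to a mask reference — either a
    file path or an in-memory :class:`~blindval.masks.BinaryMask`.
    """

    images: tuple[str, ...]
    sources: tuple[str, ...]
    masks: Mapping[tuple[str, str], object]

    def __post_init__(self):
        if len(self.images) < 1:
            raise CatalogError("catalog needs at least one image")
        if len(self.sources) < 2:
            raise CatalogError("catalog needs at least two sources")
        if len(set(self.images)) != len(self.images):
            raise CatalogError("duplicate image ids in catalog")
        if len(set(self.sources)) != len(self.sources):
            raise CatalogError("duplicate source ids in catalog")
        expected = {(i, s) for i in self.images for s in self.sources}
        got = set(self.masks)
        if got != expected:
            missing = sorted(expected - got)[:5]
            extra = sorted(got - expected)[:5]
            raise CatalogError(
                f"catalog is not a complete image x source grid "
                f"(missing e.g. {missing}, extra e.g. {extra})"
            )


@dataclass(frozen=True)
class PresentationItem:
    """One slot in the blinded schedule.

    The id is a random 128-bit token: it encodes nothing about the image,
    the source, the replicate, or even the generation order.
    """

    presentation_id: str
    position: int  # 1-based index in the schedule


@dataclass(frozen=True)
class SchedulePlan:
    items: tuple[PresentationItem, ...]
    seed: int
    duplicate_spec: Mapping[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.items)

    @property
    def presentation_ids(self) -> tuple[str, ...]:
        return tuple(it.presentation_id for it in self.items)


class ProvenanceRecord:
    """Sealed identity map: presentation id → (image, source, replicate)."""

    def __init__(self, entries: Mapping[str, Triple]):
        entries = {pid: (str(i), str(s), int(r)) for pid, (i, s, r) in entries.items()}
        triples = list(entries.values())
        if len(set(triples)) != len(triples):
            raise ProvenanceError("provenance is not a bijection: repeated triple")
        for _, (_, _, rep) in entries.items():
            if rep not in (1, 2):
                raise ProvenanceError(f"replicate must be 1 or 2, got {rep}")
        self._entries = entries

    def __getitem__(self, presentation_id: str) -> Triple:
        return self._entries[presentation_id]

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self):
        return iter(self._entries)

    def __eq__(self, other) -> bool:
        return isinstance(other, ProvenanceRecord) and self._entries == other._entries

    def items(self):
        return self._entries.items()

    def validate_against(self, plan: SchedulePlan) -> None:
        """Check plan and provenance describe the same presentation set."""
        plan_ids = set(plan.presentation_ids)
        if plan_ids != set(self._entries):
            raise ScheduleError("plan and provenance disagree on presentation ids")
        # replicate 2 only where a replicate 1 exists for the same pair
        pairs1 = {(i, s) for (i, s, r) in self._entries.values() if r == 1}
        for i, s, r in self._entries.values():
            if r == 2 and (i, s) not in pairs1:
                raise ScheduleError(f"replicate 2 of ({i}, {s}) has no replicate 1")


# ---------------------------------------------------------------------------
# manifest I/O

def read_manifest(path: str | Path) -> AnnotationCatalog:
    """Read a mask manifest CSV (columns image_id, source_id, mask_path)."""
    df = pd.read_csv(path, dtype=str)
    required = {"image_id", "source_id", "mask_path"}
    if not required.issubset(df.columns):
        raise CatalogError(f"manifest must have columns {sorted(required)}")
    base = Path(path).parent
    masks = {}
    for row in df.itertuples(index=False):
        key = (row.image_id, row.source_id)
        if key in masks:
            raise CatalogError(f"manifest lists ({key}) more than once")
        p = Path(row.mask_path)
        masks[key] = p if p.is_absolute() else base / p
    images = tuple(dict.fromkeys(df["image_id"]))
    sources = tuple(dict.fromkeys(df["source_id"]))
    return AnnotationCatalog(images=images, sources=sources, masks=masks)


def write_manifest(catalog: AnnotationCatalog, path: str | Path) -> None:
    rows = [
        {"image_id": i, "source_id": s, "mask_path": str(catalog.masks[(i, s)])}
        for i in catalog.images
        for s in catalog.sources
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# schedule construction

def _fresh_token(rng: np.random.Generator, taken: set[str]) -> str:
    while True:
        tok = "".join(f"{x:016x}" for x in rng.integers(0, 2**63, size=2))
        if tok not in taken:  # collisions are ~2^-126 but cheap to exclude
            return tok


def build_schedule(
    catalog: AnnotationCatalog,
    duplicates: Mapping[str, int] | None = None,
    seed: int = 0,
) -> tuple[SchedulePlan, ProvenanceRecord]:
    """Build the blinded, shuffled schedule and its sealed identity map.

    Every (image, source) pair appears once; for each source, ``duplicates``
    extra presentations of uniformly chosen distinct images are injected
    (replicate 2).  The final order is a uniform random permutation of all
    items, driven solely by ``seed``; the same seed reproduces the plan
    byte for byte.
    """
    duplicates = dict(duplicates or {})
    n_img = len(catalog.images)
    for src, count in duplicates.items():
        if src not in catalog.sources:
            raise ScheduleError(f"duplicate spec names unknown source {src!r}")
        if not 0 <= count <= n_img:
            raise ScheduleError(
                f"duplicate count {count} for source {src!r} exceeds image count {n_img}"
            )

    rng = np.random.default_rng(seed)
    triples: list[Triple] = [(i, s, 1) for i in catalog.images for s in catalog.sources]
    for src in catalog.sources:  # fixed source order keeps the draw reproducible
        count = duplicates.get(src, 0)
        if count:
            chosen = rng.choice(n_img, size=count, replace=False)
            triples.extend((catalog.images[int(k)], src, 2) for k in chosen)

    order = rng.permutation(len(triples))
    taken: set[str] = set()
    items = []
    entries = {}
    for pos, idx in enumerate(order, start=1):
        pid = _fresh_token(rng, taken)
        taken.add(pid)
        items.append(PresentationItem(presentation_id=pid, position=pos))
        entries[pid] = triples[int(idx)]

    plan = SchedulePlan(items=tuple(items), seed=seed, duplicate_spec=duplicates)
    prov = ProvenanceRecord(entries)
    prov.validate_against(plan)
    return plan, prov


def order_ranks(
    plan: SchedulePlan,
    prov: ProvenanceRecord,
    include_duplicates: bool = False,
) -> dict[tuple[str, str], int]:
    """Rank, per image, its sources by order of first appearance.

    For each image the first-pass (replicate-1) presentations of its
    sources are ranked 1..S by schedule position — "was this source's
    mask the first, second, or third version of this image the validator
    saw".  Covert repeats are excluded from ranking by default; with
    ``include_duplicates=True`` they occupy rank slots too (so the ranks
    reported for replicate-1 entries may exceed the number of sources).
    """
    prov.validate_against(plan)
    by_image: dict[str, list[tuple[int, str, int]]] = {}
    for item in plan.items:
        img, src, rep = prov[item.presentation_id]
        if rep == 2 and not include_duplicates:
            continue
        by_image.setdefault(img, []).append((item.position, src, rep))
    ranks: dict[tuple[str, str], int] = {}
    for img, entries in by_image.items():
        entries.sort()
        for rank, (_, src, rep) in enumerate(entries, start=1):
            if rep == 1:
                ranks[(img, src)] = rank
    return ranks


# ---------------------------------------------------------------------------
# plan / provenance persistence

_PROV_VERSION = 1


def _prov_payload(prov: ProvenanceRecord) -> dict:
    return {
        pid: {"image_id": i, "source_id": s, "replicate": r}
        for pid, (i, s, r) in sorted(prov.items())
    }


def seal(prov: ProvenanceRecord, path: str | Path) -> None:
    """Write provenance to its own file, with an integrity checksum.

    The file is the blinding boundary: nothing in the review stage may
    read it.  The checksum lets :func:`unseal` detect truncation or
    tampering.
    """
    payload = _prov_payload(prov)
    body = json.dumps(payload, sort_keys=True, separators=(",", ":"))
    digest = hashlib.sha256(body.encode()).hexdigest()
    doc = {"format": "blindval-provenance", "version": _PROV_VERSION,
           "sha256": digest, "entries": payload}
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def unseal(path: str | Path) -> ProvenanceRecord:
    """Read a sealed provenance file, verifying checksum and bijection."""
    try:
        doc = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ProvenanceError(f"cannot read provenance file {path}: {exc}") from exc
    if not isinstance(doc, dict) or doc.get("format") != "blindval-provenance":
        raise ProvenanceError(f"{path} is not a provenance file")
    entries = doc.get("entries")
    if not isinstance(entries, dict):
        raise ProvenanceError(f"{path}: missing entries")
    body = json.dumps(entries, sort_keys=True, separators=(",", ":"))
    if hashlib.sha256(body.encode()).hexdigest() != doc.get("sha256"):
        raise ProvenanceError(f"{path}: checksum mismatch (corrupt or tampered)")
    try:
        triples = {
            pid: (e["image_id"], e["source_id"], int(e["replicate"]))
            for pid, e in entries.items()
        }
    except (KeyError, TypeError, ValueError) as exc:
        raise ProvenanceError(f"{path}: malformed entry: {exc}") from exc
    return ProvenanceRecord(triples)


_BLINDED_KEYS = {"presentation_id", "position", "mask_file"}
_FORBIDDEN_KEYS = {"image_id", "source_id", "replicate", "labeler", "origin"}


def write_plan(plan: SchedulePlan, path: str | Path) -> None:
    """Write the blinded plan: an ordered array of presentation items only."""
    doc = {
        "format": "blindval-plan",
        "seed_fingerprint": hashlib.sha256(str(plan.seed).encode()).hexdigest()[:12],
        "items": [
            {"presentation_id": it.presentation_id, "position": it.position}
            for it in plan.items
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_plan(path: str | Path) -> SchedulePlan:
    try:
        doc = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ScheduleError(f"cannot read plan file {path}: {exc}") from exc
    if doc.get("format") != "blindval-plan":
        raise ScheduleError(f"{path} is not a plan file")
    items = tuple(
        PresentationItem(presentation_id=e["presentation_id"], position=int(e["position"]))
        for e in doc["items"]
    )
    # the blinded plan intentionally does not carry the seed
    return SchedulePlan(items=items, seed=-1, duplicate_spec={})


def audit_blinded_bundle(path: str | Path) -> None:
    """Schema audit of a review bundle directory: no provenance may leak.

    Checks that the plan file carries only presentation ids/positions and
    that no provenance file sits inside the bundle directory.
    """
    path = Path(path)
    plan_file = path / "plan.json" if path.is_dir() else path
    doc = json.loads(Path(plan_file).read_text())
    for entry in doc.get("items", []):
        bad = set(entry) & _FORBIDDEN_KEYS
        if bad:
            raise BlindingError(f"plan entry leaks provenance fields: {sorted(bad)}")
        unknown = set(entry) - _BLINDED_KEYS
        if unknown:
            raise BlindingError(f"plan entry has unexpected fields: {sorted(unknown)}")
    if path.is_dir():
        for p in path.rglob("*.json"):
            try:
                d = json.loads(p.read_text())
            except (OSError, json.JSONDecodeError):
                continue
            if isinstance(d, dict) and d.get("format") == "blindval-provenance":
                raise BlindingError(f"provenance file {p} found inside review bundle")


def export_blinded_bundle(
    plan: SchedulePlan,
    prov: ProvenanceRecord,
    catalog: AnnotationCatalog,
    outdir: str | Path,
) -> Path:
    """Materialise the review bundle: plan.json + masks renamed to tokens.

    Masks are *copied* under their presentation-id filename: the original
    path (which typically embeds image and source names) must not reach
    the validator.  The provenance is NOT written here; seal it elsewhere.
    """
    from . import masks as _m  # local import to avoid a cycle at import time

    outdir = Path(outdir)
    (outdir / "masks").mkdir(parents=True, exist_ok=True)
    prov.validate_against(plan)
    for item in plan.items:
        img, src, _rep = prov[item.presentation_id]
        ref = catalog.masks[(img, src)]
        dest = outdir / "masks" / f"{item.presentation_id}.png"
        if isinstance(ref, (str, Path)):
            shutil.copyfile(ref, dest)
        else:  # in-memory BinaryMask
            _m.write_mask(ref, dest)
    write_plan(plan, outdir / "plan.json")
    return outdir
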