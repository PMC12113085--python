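"""Synthetic cohorts: controllable masks, and a stochastic validator.

The generator emulates the structure of a blinded dense-tissue
validation study without any real mammograms: N images, each segmented
by S sources whose masks are perturbations of a shared base region (so
pairwise DSC is controllable), covert duplicates per source, and a
simulated validator with configurable per-source agreement, an
order-of-appearance effect, a repeat-inconsistency rate, and a session
plan with breaks.

Defaults mirror the reference study design: 500 images, three sources
(two human-like annotators L1/L2 and a model), 100 covert duplicates per
source (1800 presentations in total), perturbations placing pairwise
DSC in the 0.7–0.8 band typical of dense-tissue annotation, a repeat
flip probability of 0.04 (binary discordance 2ε(1−ε) ≈ 7.7%), and 28
review sessions of which the final two contain a single image.

Masks are smooth convex-ish regions (an ellipse with low-order boundary
wobble), not anatomically realistic tissue: only the DSC structure
matters to the downstream analyses.

Seeding is hierarchical: the master seed spawns independent streams per
image and per (image, source), so enlarging the cohort does not
reshuffle earlier images.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from typing import Mapping, Sequence

import numpy as np

from .design import (AnnotationCatalog, ProvenanceRecord, SchedulePlan,
                     build_schedule, order_ranks)
from .errors import CatalogError, ScheduleError
from .masks import BinaryMask
from .responses import DEFAULT_SCHEME, LabelScheme, ResponseLog, ValidationResponse

__all__ = [
    "CohortConfig",
    "ValidatorBehavior",
    "gen_masks",
    "simulate_validator",
    "study_session_plan",
    "simulate_study",
]

_SOURCES = ("L1", "L2", "model")


@dataclass(frozen=True)
class CohortConfig:
    """Generative parameters of a synthetic annotation cohort.

    ``perturbation`` (pixels) controls how far each source's mask strays
    from the image's base region; expected pairwise DSC decreases
    monotonically as it grows.  The defaults reproduce the reference
    design: 500 images, sources L1/L2/model, 100 duplicates per source.
    """

    n_images: int = 500
    width: int = 96
    height: int = 96
    source_ids: tuple[str, ...] = _SOURCES
    perturbation: Mapping[str, float] = field(
        default_factory=lambda: {"L1": 4.0, "L2": 4.0, "model": 6.0})
    duplicates: Mapping[str, int] = field(
        default_factory=lambda: {s: 100 for s in _SOURCES})
    seed: int = 0

    def __post_init__(self):
        if self.n_images < 1:
            raise CatalogError("n_images must be >= 1")
        if min(self.width, self.height) < 16:
            raise CatalogError("raster too small for a non-degenerate region")
        if any(p < 0 for p in self.perturbation.values()):
            raise CatalogError("perturbation must be non-negative")


def _wobbly_ellipse(
    width: int, height: int,
    cx: float, cy: float, rx: float, ry: float, theta: float,
    wobble_amp: float, wobble_phase: np.ndarray,
) -> np.ndarray:
    """Boolean raster of an ellipse whose radius wobbles sinusoidally."""
    if rx <= 1 or ry <= 1:
        raise CatalogError("degenerate region: zero-area ellipse")
    yy, xx = np.mgrid[0:height, 0:width]
    dx, dy = xx - cx, yy - cy
    ct, st = np.cos(theta), np.sin(theta)
    u = (dx * ct + dy * st) / rx
    v = (-dx * st + dy * ct) / ry
    r = np.hypot(u, v)
    ang = np.arctan2(v, u)
    # low-order boundary wobble, relative amplitude
    bound = 1.0 + wobble_amp * (
        np.sin(2 * ang + wobble_phase[0]) + 0.5 * np.sin(3 * ang + wobble_phase[1])
    )
    return r <= bound


def gen_masks(config: CohortConfig) -> AnnotationCatalog:
    """Generate the full image × source grid of in-memory masks.

    Per image a base region (ellipse + wobble) is drawn; per source the
    region's centre, axes and wobble phases are jittered by the source's
    perturbation magnitude.  Fully reproducible from ``config.seed``.
    """
    w, h = config.width, config.height
    images = tuple(f"img{i:04d}" for i in range(config.n_images))
    masks: dict[tuple[str, str], BinaryMask] = {}
    for i, img in enumerate(images):
        rng = np.random.default_rng([config.seed, 1, i])
        cx = w / 2 + rng.uniform(-0.08, 0.08) * w
        cy = h / 2 + rng.uniform(-0.08, 0.08) * h
        rx = rng.uniform(0.22, 0.34) * w
        ry = rng.uniform(0.22, 0.34) * h
        theta = rng.uniform(0, np.pi)
        phase = rng.uniform(0, 2 * np.pi, size=2)
        for s_idx, src in enumerate(config.source_ids):
            srng = np.random.default_rng([config.seed, 2, i, s_idx])
            p = float(config.perturbation.get(src, 0.0))
            data = _wobbly_ellipse(
                w, h,
                cx + srng.normal(0, p), cy + srng.normal(0, p),
                # jitter cannot annihilate the region: axes floor at 2 px
                max(2.0, rx + srng.normal(0, p)), max(2.0, ry + srng.normal(0, p)),
                theta + srng.normal(0, p * 0.02),
                wobble_amp=0.02 + 0.01 * p,
                wobble_phase=phase + srng.normal(0, p * 0.2, size=2),
            )
            masks[(img, src)] = BinaryMask(image_id=img, source_id=src, data=data)
    return AnnotationCatalog(images=images, sources=tuple(config.source_ids),
                             masks=masks)


@dataclass(frozen=True)
class ValidatorBehavior:
    """Stochastic model of the blinded validator.

    A latent binary judgment (agree/disagree) is drawn once per
    (image, source) with probability base_agree[source] + rank_offsets[r−1]
    (clipped to [0, 1]), where r is the mask's order of appearance among
    the image's versions.  Each *evaluation* of the item then flips the
    binary judgment independently with probability ``flip_prob``, so two
    evaluations of a covert repeat disagree with probability 2ε(1−ε).
    Disagree evaluations pick a category from ``disagree_split``.

    ``session_plan`` is a sequence of (n_items, gap_seconds_after); None
    selects the default 28-session plan of the reference design.
    """

    base_agree: Mapping[str, float] = field(
        default_factory=lambda: {"L1": 0.85, "L2": 0.83, "model": 0.83})
    disagree_split: Mapping[str, float] = field(
        default_factory=lambda: {"oversegmented": 0.5, "undersegmented": 0.4,
                                 "incorrect": 0.1})
    flip_prob: float = 0.04
    rank_offsets: tuple[float, ...] = (0.0, 0.0, 0.0)
    session_plan: Sequence[tuple[int, float]] | None = None
    item_seconds: float = 45.0
    seed: int = 0

    def __post_init__(self):
        for p in self.base_agree.values():
            if not 0.0 <= p <= 1.0:
                raise ScheduleError("base agree probabilities must lie in [0, 1]")
        if not 0.0 <= self.flip_prob <= 1.0:
            raise ScheduleError("flip_prob must lie in [0, 1]")
        tot = sum(self.disagree_split.values())
        if not np.isclose(tot, 1.0):
            raise ScheduleError(f"disagree_split must sum to 1, got {tot}")


def study_session_plan(
    n_items: int,
    n_sessions: int = 28,
    gap_seconds: float = 2.5 * 3600,
) -> list[tuple[int, float]]:
    """Split a run into review sessions separated by >1 h breaks.

    Mirrors the reference study's structure: the final two sessions hold
    a single item each, the rest share the remaining items as evenly as
    possible.  All inter-session gaps exceed one hour so the session
    detector must recover exactly ``n_sessions``.
    """
    if n_sessions < 1 or n_items < n_sessions:
        raise ScheduleError("need at least one item per session")
    sizes: list[int]
    if n_sessions >= 3 and n_items > n_sessions:
        bulk = n_sessions - 2
        rest = n_items - 2
        base, extra = divmod(rest, bulk)
        sizes = [base + (1 if i < extra else 0) for i in range(bulk)] + [1, 1]
    else:
        base, extra = divmod(n_items, n_sessions)
        sizes = [base + (1 if i < extra else 0) for i in range(n_sessions)]
    return [(sz, gap_seconds) for sz in sizes]


def simulate_validator(
    plan: SchedulePlan,
    prov: ProvenanceRecord,
    behavior: ValidatorBehavior,
    scheme: LabelScheme = DEFAULT_SCHEME,
    start: datetime | None = None,
) -> ResponseLog:
    """Walk the schedule and emit a complete stochastic response log."""
    prov.validate_against(plan)
    ranks = order_ranks(plan, prov)
    rng = np.random.default_rng([behavior.seed, 3])
    disagree_cats = [c for c in scheme.categories if c in behavior.disagree_split]
    if not disagree_cats or set(disagree_cats) - set(scheme.disagree):
        raise ScheduleError("disagree_split categories must be disagree labels of the scheme")
    split = np.array([behavior.disagree_split[c] for c in disagree_cats])
    agree_cats = sorted(scheme.agree)

    def draw_agree_label() -> str:
        return (agree_cats[0] if len(agree_cats) == 1
                else agree_cats[int(rng.integers(len(agree_cats)))])

    def draw_disagree_label() -> str:
        return disagree_cats[int(rng.choice(len(disagree_cats), p=split))]

    # latent judgment (full label, category included) per (image, source);
    # a repeat evaluation only changes it via an explicit binary flip
    latent: dict[tuple[str, str], str] = {}
    for (img, src), rank in sorted(ranks.items()):
        base = behavior.base_agree.get(src, 0.8)
        off = (behavior.rank_offsets[rank - 1]
               if rank - 1 < len(behavior.rank_offsets) else 0.0)
        p = float(np.clip(base + off, 0.0, 1.0))
        latent[(img, src)] = (draw_agree_label() if rng.random() < p
                              else draw_disagree_label())

    session_plan = (list(behavior.session_plan) if behavior.session_plan is not None
                    else study_session_plan(len(plan)))
    if sum(sz for sz, _ in session_plan) != len(plan):
        raise ScheduleError(
            f"session plan covers {sum(sz for sz, _ in session_plan)} items, "
            f"schedule has {len(plan)}")

    clock = start or datetime(2024, 1, 8, 9, 0, tzinfo=timezone.utc)
    log = ResponseLog(scheme=scheme)
    items = iter(plan.items)
    for size, gap in session_plan:
        for _ in range(size):
            item = next(items)
            img, src, _rep = prov[item.presentation_id]
            label = latent[(img, src)]
            if rng.random() < behavior.flip_prob:  # per-evaluation flip
                label = (draw_disagree_label() if label in scheme.agree
                         else draw_agree_label())
            dwell = float(rng.gamma(4.0, behavior.item_seconds / 4.0)) + 2.0
            shown = clock
            answered = shown + timedelta(seconds=dwell)
            log.append(ValidationResponse(
                presentation_id=item.presentation_id, label=label,
                shown_at=shown, answered_at=answered,
            ))
            clock = answered + timedelta(seconds=float(rng.uniform(1, 5)))
        clock = clock + timedelta(seconds=float(gap))
    return log


def simulate_study(
    config: CohortConfig | None = None,
    behavior: ValidatorBehavior | None = None,
    scheme: LabelScheme = DEFAULT_SCHEME,
    with_masks: bool = True,
):
    """End-to-end synthetic run: masks → schedule → provenance → responses.

    Returns (catalog, plan, provenance, log).  ``with_masks=False`` skips
    mask rasterisation for analyses that only need labels (order effects,
    repeats, sessions), which makes large-N simulations cheap.
    """
    config = config or CohortConfig()
    behavior = behavior or ValidatorBehavior(seed=config.seed)
    if with_masks:
        catalog = gen_masks(config)
    else:
        images = tuple(f"img{i:04d}" for i in range(config.n_images))
        masks = {(i, s): None for i in images for s in config.source_ids}
        catalog = AnnotationCatalog(images=images,
                                    sources=tuple(config.source_ids), masks=masks)
    plan, prov = build_schedule(catalog, config.duplicates, seed=config.seed)
    log = simulate_validator(plan, prov, behavior, scheme)
    return catalog, plan, prov, log
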