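"""Binary glyph stimuli: generation, cardinal rotation, manifests and raster I/O.

The visual material is a bank of simple black-and-white glyphs (letters,
dots, lines) on a square pixel grid, each expanded into rotation variants
at the cardinal angles 0/90/180/270 degrees.  The canonical bank packaged
with this module contains 12 glyph groups expanding to 39 distinct stimuli;
a learning/evaluation split assigns 6 groups to the familiar (learned) set
and 6 to the novel (evaluation-only) set, with the dot, two-dot and line
groups always familiar because they open the learning sequence.

Images follow standard raster convention: row 0 is the top of the image,
column 0 the left.  Brightness is in [0, 1]; canonical stimuli are binary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from PIL import Image as _PILImage

__all__ = [
    "PixelImage",
    "GlyphSpec",
    "StimulusSet",
    "FamiliarityPartition",
    "FIRST_GROUPS",
    "rotate_image",
    "expand_group",
    "load_manifest",
    "build_stimulus_set",
    "canonical_stimulus_set",
    "split_familiar_novel",
    "read_raster",
    "write_raster",
]

#: groups that open the learning sequence and are always in the familiar set:
#: the single dot, the two-dot pair, and the line.
FIRST_GROUPS = ("DOT", "PP", "D")

CARDINAL_ANGLES = (0, 90, 180, 270)

# PixelImage is a plain 2-D float array in [0, 1]; helpers below validate it.
PixelImage = np.ndarray


def as_pixel_image(pixels, *, size: int | None = None) -> PixelImage:
    """Validate and coerce ``pixels`` into a square float image in [0, 1]."""
    img = np.asarray(pixels, dtype=float)
    if img.ndim != 2:
        raise ValueError(f"image must be 2-D, got shape {img.shape}")
    if img.shape[0] != img.shape[1]:
        raise ValueError(f"image must be square, got shape {img.shape}")
    if size is not None and img.shape[0] != size:
        raise ValueError(f"image must be {size}x{size}, got {img.shape}")
    if img.min() < 0.0 or img.max() > 1.0:
        raise ValueError("brightness values must lie in [0, 1]")
    return img


def rotate_image(image: PixelImage, angle: int) -> PixelImage:
    """Rotate a square image clockwise by a cardinal angle, losslessly.

    Rotation is the exact index permutation (r, c) -> (c, n-1-r) per quarter
    turn — a bijection on pixel coordinates, so total brightness is
    conserved and no interpolation ever occurs.  0 degrees is the identity.
    """
    img = as_pixel_image(image)
    if angle not in CARDINAL_ANGLES:
        raise ValueError(
            f"angle must be one of {CARDINAL_ANGLES} degrees, got {angle!r}; "
            "oblique rotations are not supported"
        )
    return np.rot90(img, k=-(angle // 90)).copy()


@dataclass(frozen=True)
class GlyphSpec:
    """One glyph group: a base bitmap plus the rotation angles retained.

    ``variant_angles`` lists the cardinal rotations kept as distinct
    stimuli.  For fully listed orbits, every unlisted rotation reproduces a
    listed bitmap (symmetry closure); groups such as the off-centre two-dot
    pair retain only a subset of a 4-element orbit, so closure is reported
    by :meth:`symmetry_closed` rather than enforced.
    """

    group_id: str
    base_bitmap: PixelImage
    variant_angles: tuple[int, ...]

    def __post_init__(self):
        object.__setattr__(self, "base_bitmap", as_pixel_image(self.base_bitmap))
        angles = tuple(self.variant_angles)
        if not angles:
            raise ValueError(f"group {self.group_id!r}: variant_angles is empty")
        bad = [a for a in angles if a not in CARDINAL_ANGLES]
        if bad:
            raise ValueError(f"group {self.group_id!r}: non-cardinal angles {bad}")
        if len(set(angles)) != len(angles):
            raise ValueError(f"group {self.group_id!r}: duplicate angles")
        object.__setattr__(self, "variant_angles", angles)

    def variant_bitmaps(self) -> list[PixelImage]:
        return [rotate_image(self.base_bitmap, a) for a in self.variant_angles]

    def symmetry_closed(self) -> bool:
        """True if every unlisted cardinal rotation reproduces a listed bitmap."""
        listed = self.variant_bitmaps()
        for a in CARDINAL_ANGLES:
            if a in self.variant_angles:
                continue
            rot = rotate_image(self.base_bitmap, a)
            if not any(np.array_equal(rot, b) for b in listed):
                return False
        return True


def expand_group(spec: GlyphSpec) -> list[tuple[str, int, PixelImage]]:
    """Expand a glyph group into (stimulus_id, angle, bitmap) variants.

    Ids are formed as group_id + angle (e.g. ``"E90"``).  Raises if two
    declared angles yield identical bitmaps (misdeclared symmetry).
    """
    out = []
    seen: list[PixelImage] = []
    for angle in spec.variant_angles:
        bitmap = rotate_image(spec.base_bitmap, angle)
        for prev_id, _, prev in out:
            if np.array_equal(bitmap, prev):
                raise ValueError(
                    f"group {spec.group_id!r}: angle {angle} duplicates variant "
                    f"{prev_id!r}; symmetry is misdeclared"
                )
        out.append((f"{spec.group_id}{angle}", angle, bitmap))
        seen.append(bitmap)
    return out


@dataclass(frozen=True)
class StimulusSet:
    """Ordered stimulus bank: expanded variants plus their glyph groups."""

    stimuli: tuple[tuple[str, str, int, PixelImage], ...]  # (id, group, angle, image)
    groups: tuple[GlyphSpec, ...]

    @property
    def ids(self) -> list[str]:
        return [s[0] for s in self.stimuli]

    @property
    def group_ids(self) -> list[str]:
        return [g.group_id for g in self.groups]

    def image(self, stimulus_id: str) -> PixelImage:
        for sid, _, _, img in self.stimuli:
            if sid == stimulus_id:
                return img
        raise KeyError(f"unknown stimulus id {stimulus_id!r}")

    def group_of(self, stimulus_id: str) -> str:
        for sid, gid, _, _ in self.stimuli:
            if sid == stimulus_id:
                return gid
        raise KeyError(f"unknown stimulus id {stimulus_id!r}")

    def ids_in_group(self, group_id: str) -> list[str]:
        return [sid for sid, gid, _, _ in self.stimuli if gid == group_id]

    def __len__(self) -> int:
        return len(self.stimuli)


def load_manifest(source) -> dict:
    """Load a stimulus manifest from a path, JSON string, or mapping."""
    if isinstance(source, dict):
        return source
    if isinstance(source, (str, Path)) and Path(str(source)).exists():
        with open(source) as fh:
            return json.load(fh)
    if isinstance(source, str):
        return json.loads(source)
    raise TypeError(f"cannot interpret manifest source of type {type(source)!r}")


def _bitmap_from_manifest(entry: dict, image_size: int, scale: int) -> PixelImage:
    if "bitmap" in entry:
        rows = entry["bitmap"]
        small = np.array([[float(ch) for ch in row] for row in rows])
    elif "path" in entry:
        small = read_raster(entry["path"])
    else:
        raise ValueError(f"group {entry.get('group_id')!r}: no bitmap or path")
    if scale > 1:
        small = np.kron(small, np.ones((scale, scale)))
    return as_pixel_image(small, size=image_size)


def build_stimulus_set(
    manifest,
    *,
    expect_groups: int | None = None,
    expect_stimuli: int | None = None,
) -> StimulusSet:
    """Expand a manifest of glyph groups into a validated StimulusSet.

    Ordering is deterministic: manifest group order, then declared angle
    order.  All expanded bitmaps must be pairwise distinct across the whole
    set.  When the expected canonical totals are given, a mismatch raises a
    validation error listing the per-group counts.
    """
    data = load_manifest(manifest)
    entries = data.get("groups", [])
    if not entries:
        raise ValueError("manifest declares no glyph groups")
    size = int(data.get("image_size", 64))
    scale = int(data.get("scale", 1))

    groups = []
    stimuli = []
    for entry in entries:
        spec = GlyphSpec(
            group_id=str(entry["group_id"]),
            base_bitmap=_bitmap_from_manifest(entry, size, scale),
            variant_angles=tuple(int(a) for a in entry["variant_angles"]),
        )
        groups.append(spec)
        for sid, angle, bitmap in expand_group(spec):
            stimuli.append((sid, spec.group_id, angle, bitmap))

    ids = [s[0] for s in stimuli]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate stimulus ids across groups")
    for i in range(len(stimuli)):
        for j in range(i + 1, len(stimuli)):
            if np.array_equal(stimuli[i][3], stimuli[j][3]):
                raise ValueError(
                    f"stimuli {stimuli[i][0]!r} and {stimuli[j][0]!r} have "
                    "identical bitmaps"
                )

    counts = {g.group_id: len(g.variant_angles) for g in groups}
    if expect_groups is not None and len(groups) != expect_groups:
        raise ValueError(
            f"expected {expect_groups} groups, got {len(groups)}: {counts}"
        )
    if expect_stimuli is not None and len(stimuli) != expect_stimuli:
        raise ValueError(
            f"expected {expect_stimuli} stimuli, got {len(stimuli)}: {counts}"
        )
    return StimulusSet(stimuli=tuple(stimuli), groups=tuple(groups))


def canonical_manifest() -> dict:
    """The packaged canonical manifest: 12 groups, 39 stimuli."""
    text = resources.files("sonoglyph.data").joinpath("canonical_manifest.json").read_text()
    return json.loads(text)


def canonical_stimulus_set() -> StimulusSet:
    """Build the canonical 12-group / 39-stimulus bank, fully validated."""
    return build_stimulus_set(canonical_manifest(), expect_groups=12, expect_stimuli=39)


@dataclass(frozen=True)
class FamiliarityPartition:
    """Split of glyph groups into familiar (learned) and novel halves."""

    familiar_groups: tuple[str, ...]
    novel_groups: tuple[str, ...]
    familiar_ids: tuple[str, ...] = field(default=())
    novel_ids: tuple[str, ...] = field(default=())

    def is_familiar(self, stimulus_id: str) -> bool:
        if stimulus_id in self.familiar_ids:
            return True
        if stimulus_id in self.novel_ids:
            return False
        raise KeyError(f"unknown stimulus id {stimulus_id!r}")


def split_familiar_novel(
    stimulus_set: StimulusSet,
    seed: int,
    *,
    n_familiar: int = 6,
    forced_groups: tuple[str, ...] = FIRST_GROUPS,
) -> FamiliarityPartition:
    """Seeded random selection of the learned groups; remainder are novel.

    The dot, two-dot and line groups are forced into the familiar set (they
    open the learning sequence); the remaining familiar slots are drawn
    uniformly from the other groups.
    """
    gids = stimulus_set.group_ids
    if len(gids) < 2:
        raise ValueError("need at least 2 groups to partition")
    forced = tuple(g for g in forced_groups if g in gids)
    if len(forced) > n_familiar:
        raise ValueError("more forced groups than familiar slots")
    pool = [g for g in gids if g not in forced]
    rng = np.random.default_rng(seed)
    extra = sorted(rng.choice(len(pool), size=n_familiar - len(forced), replace=False))
    familiar = forced + tuple(pool[i] for i in extra)
    novel = tuple(g for g in gids if g not in familiar)
    return FamiliarityPartition(
        familiar_groups=familiar,
        novel_groups=novel,
        familiar_ids=tuple(
            sid for sid, gid, _, _ in stimulus_set.stimuli if gid in familiar
        ),
        novel_ids=tuple(
            sid for sid, gid, _, _ in stimulus_set.stimuli if gid in novel
        ),
    )


def read_raster(path) -> PixelImage:
    """Read a grayscale PGM/PNG raster into a [0, 1] square image."""
    with _PILImage.open(path) as im:
        if im.mode not in ("L", "1", "I", "I;16"):
            raise ValueError(
                f"{path}: mode {im.mode!r} is not grayscale; only single-channel "
                "rasters are supported"
            )
        arr = np.asarray(im.convert("L"), dtype=float) / 255.0
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError(f"{path}: image must be square, got shape {arr.shape}")
    return arr


def write_raster(image: PixelImage, path) -> None:
    """Write a [0, 1] image as an 8-bit grayscale PGM (P5) or PNG."""
    img = as_pixel_image(image)
    data = np.round(img * 255.0).astype(np.uint8)
    pil = _PILImage.fromarray(data, mode="L")
    path = Path(path)
    fmt = {"pgm": "PPM", "pnm": "PPM", "png": "PNG"}.get(path.suffix.lstrip(".").lower())
    if fmt is None:
        raise ValueError(f"unsupported raster extension {path.suffix!r}; use .pgm or .png")
    pil.save(path, format=fmt)
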