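"""End-to-end animation jobs: map + data + camera -> video or frame files.

The pipeline is: read map -> (merge model) -> read data -> match
identifiers -> interpolate -> sample frame values -> encode -> camera ->
render -> mux.  The frame count is ``round(duration_s * fps)``.

Containers
----------
Guaranteed everywhere: a PNG frame sequence (``frames_dir``) and a
multi-page TIFF — both lossless, frame-exact and decodable with Pillow,
which makes them the testable reference path.  Animated GIF is also
written without extra dependencies, with two format caveats: colors are
palette-quantized and consecutive *identical* frames are coalesced by the
GIF writer.  MP4/AVI/MOV/MKV are attempted through imageio's ffmpeg
backend when one is installed; when it is not, the job fails with an error
naming the missing capability rather than silently degrading.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
from PIL import Image

from . import camera as cam
from . import timecourse as tc
from .encoding import EncodingConfig, encode, series_bounds
from .escher import GZIP_MAGIC, read_escher_json
from .maps import MetabolicMap
from .render import Frame, RenderStyle, compose_legend, render_frame
from .sbml_layout import merge_layout_into_model, read_sbml, read_sbml_layout

__all__ = ["AnimationJob", "AnimationResult", "run_animation", "probe_output",
           "load_map_any", "ContainerError"]

log = logging.getLogger(__name__)

GIF_CONTAINERS = {".gif"}
TIFF_CONTAINERS = {".tif", ".tiff"}
FFMPEG_CONTAINERS = {".mp4", ".avi", ".mov", ".mkv", ".mpg", ".wmv", ".flv"}


class ContainerError(RuntimeError):
    """Requested output container cannot be produced (missing codec/backend)."""


@dataclass
class AnimationJob:
    """Everything needed to produce one animation."""

    map_source: Union[str, Path, MetabolicMap]
    data_source: Union[str, Path, bytes]
    model_source: Optional[Union[str, Path]] = None
    camera_source: Optional[Union[str, Path]] = None
    encoding: EncodingConfig = field(default_factory=EncodingConfig)
    style: RenderStyle = field(default_factory=RenderStyle)
    duration_s: float = 10.0
    fps: float = 15.0
    output: Optional[Union[str, Path]] = None
    frames_dir: Optional[Union[str, Path]] = None
    interpolation: str = "cubic-spline"
    #: overlay a running time stamp / colorbar; off by default so that
    #: constant data yields bit-identical frames
    legend: bool = False
    camera_policy: str = "free"

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if not 1 <= self.fps <= 120:
            raise ValueError("fps must be within [1, 120]")
        if self.output is None and self.frames_dir is None:
            raise ValueError("either output or frames_dir must be given")


@dataclass
class AnimationResult:
    """Exit report of a finished job."""

    n_frames: int
    match_report: tc.MatchReport
    output: Optional[Path]
    frames_dir: Optional[Path]
    frame_digest: str  # sha256 over all pre-mux frame buffers


def load_map_any(source: Union[str, Path, MetabolicMap]) -> MetabolicMap:
    """Load a map from Escher JSON or SBML Layout, sniffing the format."""
    if isinstance(source, MetabolicMap):
        return source
    raw = Path(source).read_bytes()
    probe = raw[:2]
    if probe == GZIP_MAGIC:
        import gzip

        probe = gzip.decompress(raw)[:2]
    if probe.lstrip().startswith(b"<"):
        m, _doc = read_sbml_layout(raw if probe == raw[:2] else raw)
        return m
    return read_escher_json(source)


def _iter_frames(job: AnimationJob):
    """Yield rendered frames lazily; returns metadata via StopIteration value."""
    metabolic_map = load_map_any(job.map_source)

    if job.model_source is not None and not isinstance(job.map_source, MetabolicMap):
        # merging is only meaningful when the map came from a convertible doc;
        # the merged document is a side artifact, the in-memory map drives drawing
        try:
            from .sbml_layout import escher_to_sbml_layout

            model_doc = read_sbml(job.model_source)
            layout_doc = escher_to_sbml_layout(metabolic_map, model_doc)
            _merged, glyph_report = merge_layout_into_model(model_doc, layout_doc)
            log.info("model merge: %s", glyph_report.summary())
        except Exception as exc:  # merge failures must not kill the animation
            log.warning("model merge skipped: %s", exc)

    table = tc.read_timecourse_csv(job.data_source)
    report = tc.match_identifiers(table, metabolic_map)
    if not report.matched:
        log.warning("no matched metabolites; producing an unanimated map")

    interp = tc.build_interpolants(table, method=job.interpolation)
    frame_times, ids, matrix = tc.sample_frames(interp, job.duration_s, job.fps)
    n_frames = len(frame_times)

    bounds = series_bounds(matrix, ids, job.encoding)

    # node_id -> column index, honouring suffix-stripping aliases
    bigg_to_node = {n.bigg_id: n.node_id for n in metabolic_map.metabolite_nodes()}
    col_of_node: dict[str, int] = {}
    for j, mid in enumerate(ids):
        if mid not in report.matched:
            continue
        bigg = report.aliases.get(mid, mid)
        node_id = bigg_to_node.get(bigg)
        if node_id is not None:
            col_of_node[node_id] = j

    if job.camera_source is not None:
        path = cam.read_camera_file(job.camera_source)
    else:  # static full-canvas camera
        c = metabolic_map.canvas
        zoom = max(c.width / job.style.width, c.height / job.style.height)
        path = cam.CameraPath(zoom=zoom, corners=[(c.x, c.y)])

    dims = (job.style.width, job.style.height)
    for i in range(n_frames):
        u = i / (n_frames - 1) if n_frames > 1 else 0.0
        vp = cam.clamp_viewport(
            cam.viewport_at(path, u, dims), metabolic_map.canvas, job.camera_policy
        )
        states = {}
        for node_id, j in col_of_node.items():
            mid = ids[j]
            lo, hi = bounds[mid]
            states[node_id] = encode(float(matrix[i, j]), lo, hi, job.encoding)
        frame = render_frame(
            metabolic_map, states, vp, job.style, job.encoding,
            index=i, data_time=float(frame_times[i]),
        )
        if job.legend:
            frame = compose_legend(frame, job.encoding, frame.data_time, job.style)
        yield frame
    return report


def run_animation(job: AnimationJob) -> AnimationResult:
    """Run the full pipeline and write the requested output.

    Writes a frame directory (``frame_00000.png`` ...) and/or a container
    file chosen by the output suffix.  Returns the exit report with the
    identifier match summary and the number of frames produced.
    """
    import hashlib

    frames_dir = Path(job.frames_dir) if job.frames_dir is not None else None
    output = Path(job.output) if job.output is not None else None
    if output is not None:
        suffix = output.suffix.lower()
        if suffix not in GIF_CONTAINERS | TIFF_CONTAINERS | FFMPEG_CONTAINERS:
            raise ContainerError(
                f"unsupported container {suffix!r}; use .tiff, .gif, a frame "
                f"directory, or one of {sorted(FFMPEG_CONTAINERS)} with an "
                "ffmpeg backend"
            )
        if suffix in FFMPEG_CONTAINERS:
            try:
                import imageio_ffmpeg  # noqa: F401
            except ImportError:
                raise ContainerError(
                    f"writing {suffix} requires the imageio-ffmpeg backend, "
                    "which is not installed; write .gif or use frames_dir instead"
                ) from None
    if frames_dir is not None:
        frames_dir.mkdir(parents=True, exist_ok=True)

    digest = hashlib.sha256()
    images: list[np.ndarray] = []
    gen = _iter_frames(job)
    report = None
    n = 0
    while True:
        try:
            frame = next(gen)
        except StopIteration as stop:
            report = stop.value
            break
        digest.update(frame.image.tobytes())
        if frames_dir is not None:
            Image.fromarray(frame.image, "RGB").save(
                frames_dir / f"frame_{frame.index:05d}.png"
            )
        if output is not None:
            images.append(frame.image)
        n += 1

    if output is not None:
        _mux(images, output, job.fps)
    log.info("animation done: %d frames; %s", n, report.summary())
    return AnimationResult(
        n_frames=n,
        match_report=report,
        output=output,
        frames_dir=frames_dir,
        frame_digest=digest.hexdigest(),
    )


def _mux(images: list[np.ndarray], output: Path, fps: float) -> None:
    suffix = output.suffix.lower()
    if suffix in TIFF_CONTAINERS:
        pil = [Image.fromarray(a, "RGB") for a in images]
        pil[0].save(
            output,
            save_all=True,
            append_images=pil[1:],
            description=json.dumps({"fps": fps}),
            compression="tiff_deflate",
        )
        return
    if suffix == ".gif":
        pil = [Image.fromarray(a, "RGB") for a in images]
        # exact per-frame duration in ms; disposal=2 keeps frames independent
        pil[0].save(
            output,
            save_all=True,
            append_images=pil[1:],
            duration=int(round(1000.0 / fps)),
            loop=0,
            disposal=2,
        )
        return
    import imageio.v3 as iio

    try:
        iio.imwrite(output, np.stack(images), fps=fps, plugin="FFMPEG")
    except Exception as exc:
        raise ContainerError(f"failed to write {suffix} container: {exc}") from exc


def probe_output(path: Union[str, Path]) -> dict:
    """Read container metadata: frame count, fps, pixel dimensions.

    Works on a frame directory, an animated GIF, or (with an ffmpeg
    backend) any video container imageio can open.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    if p.is_dir():
        pngs = sorted(p.glob("frame_*.png"))
        if not pngs:
            raise ContainerError(f"no frame_*.png files in {p}")
        with Image.open(pngs[0]) as im:
            w, h = im.size
        return {"n_frames": len(pngs), "fps": None, "width": w, "height": h}
    if p.suffix.lower() in TIFF_CONTAINERS:
        with Image.open(p) as im:
            n = getattr(im, "n_frames", 1)
            w, h = im.size
            desc = im.tag_v2.get(270, "") if hasattr(im, "tag_v2") else ""
        fps = None
        try:
            fps = json.loads(desc).get("fps")
        except (ValueError, AttributeError):
            pass
        return {"n_frames": n, "fps": fps, "width": w, "height": h}
    if p.suffix.lower() == ".gif":
        with Image.open(p) as im:
            n = getattr(im, "n_frames", 1)
            w, h = im.size
            duration_ms = im.info.get("duration", 0)
        fps = 1000.0 / duration_ms if duration_ms else None
        return {"n_frames": n, "fps": fps, "width": w, "height": h}
    try:
        import imageio.v3 as iio

        meta = iio.immeta(p, plugin="FFMPEG")
        frames = iio.imread(p, plugin="FFMPEG")
        return {
            "n_frames": frames.shape[0],
            "fps": meta.get("fps"),
            "width": frames.shape[2],
            "height": frames.shape[1],
        }
    except Exception as exc:
        raise ContainerError(f"cannot probe container {p}: {exc}") from exc


def decode_frames(path: Union[str, Path]) -> list[np.ndarray]:
    """Decode all frames of a GIF or frame directory to RGB arrays."""
    p = Path(path)
    if p.is_dir():
        return [
            np.asarray(Image.open(f).convert("RGB"), dtype=np.uint8)
            for f in sorted(p.glob("frame_*.png"))
        ]
    out = []
    with Image.open(p) as im:
        for i in range(getattr(im, "n_frames", 1)):
            im.seek(i)
            out.append(np.asarray(im.convert("RGB"), dtype=np.uint8))
    return out
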