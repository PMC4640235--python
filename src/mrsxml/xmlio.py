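"""Serialization: exchange XML, schema validation, config templates.

One XML file holds one DATASET: a ``Preprocessing`` history (one element
per applied step — a step that was not performed is simply absent — plus
the always-required ``AdditionalInformation``) and exactly one payload,
``Voxel`` for single-voxel or ``Grid`` for multi-voxel data.  Grid voxels
carry 1-based ``Xaxis``/``Yaxis``/``Zaxis`` position attributes with
``Zaxis`` fixed at 1 (single-slice grids).

The format is self-descriptive and anonymized by construction: the shipped
XSD (``data/mrsxml.xsd``) defines every permitted element and has no field
where a patient identifier could ride along.

Numeric encoding: doubles are printed with 17 significant digits, which
round-trips IEEE double precision exactly; spectra are stored as
whitespace-separated alternating real/imaginary pairs (``storage="complex"``)
or plain values (``storage="real"``).  The ppm axis is stored compactly as
``(ppm_first, ppm_step, points)`` under the uniform-grid invariant.
"""

from __future__ import annotations

import datetime as _dt
from importlib import resources

import numpy as np
from lxml import etree

from .config import (
    AdditionalConfig,
    AlignmentConfig,
    ApodizeConfig,
    BaselineConfig,
    ChangePointsConfig,
    ConfigTemplate,
    NormalizationConfig,
    OutputRangeConfig,
    SetReferenceConfig,
    SetToZeroConfig,
    WaterFilterConfig,
)
from .errors import ParameterError, ValidationError
from .model import (
    AcquisitionParams,
    AdditionalInfo,
    Dataset,
    GridRecord,
    PpmAxis,
    PpmRange,
    PreprocessingRecord,
    SnrResult,
    Spectrum,
    StepId,
    StepRecord,
    VoxelRecord,
    DEFAULT_LABEL,
)

__all__ = [
    "export_dataset",
    "read_dataset",
    "validate",
    "save_config",
    "load_config",
    "set_voxel_label",
    "write_canonical_ascii",
]


def _fmt(x) -> str:
    return format(float(x), ".17g")


_SCHEMA = None


def _schema() -> etree.XMLSchema:
    global _SCHEMA
    if _SCHEMA is None:
        with resources.files("mrsxml.data").joinpath("mrsxml.xsd").open("rb") as fh:
            _SCHEMA = etree.XMLSchema(etree.parse(fh))
    return _SCHEMA


# ---------------------------------------------------------------------------
# step record <-> element

def _region_el(parent, tag, upper, lower) -> None:
    etree.SubElement(parent, tag, upper=_fmt(upper), lower=_fmt(lower))


def _step_to_element(step: StepRecord) -> etree._Element:
    p = step.parameters
    el = etree.Element(step.step_id.name)
    if step.step_id == StepId.SetReference:
        el.set("reference_ppm", _fmt(p["reference_ppm"]))
    elif step.step_id == StepId.Apodize:
        el.set("shape", p["shape"])
        el.set("linewidth_hz", _fmt(p["linewidth_hz"]))
    elif step.step_id == StepId.WaterFiltering:
        el.set("n_lorentzians", str(int(p["n_lorentzians"])))
        for u, l in p["regions"]:
            _region_el(el, "Region", u, l)
    elif step.step_id == StepId.BaselineCorrection:
        for u, l in p["regions"]:
            _region_el(el, "Region", u, l)
    elif step.step_id == StepId.ChangePoints:
        el.set("target_points", str(int(p["target_points"])))
        _region_el(el, "Region", *p["range"])
    elif step.step_id == StepId.SetToZero:
        for u, l in p["intervals"]:
            _region_el(el, "Region", u, l)
    elif step.step_id == StepId.Normalization:
        el.set("norm", "l2")
    elif step.step_id == StepId.AlignmentCorrection:
        el.set("max_shift", str(int(p["max_shift"])))
        for ppm in p["peaks"]:
            peak = etree.SubElement(el, "Peak")
            peak.text = _fmt(ppm)
        _region_el(el, "NoiseRegion", *p["noise_range"])
    elif step.step_id == StepId.OutputRange:
        _region_el(el, "Region", *p["range"])
    return el


def _regions_of(el, tag="Region"):
    return [[float(r.get("upper")), float(r.get("lower"))] for r in el.findall(tag)]


def _element_to_step(el) -> StepRecord:
    try:
        sid = StepId[el.tag]
    except KeyError:
        raise ValidationError(f"unknown preprocessing step element <{el.tag}>")
    if sid == StepId.SetReference:
        p = {"reference_ppm": float(el.get("reference_ppm"))}
    elif sid == StepId.Apodize:
        p = {"shape": el.get("shape"), "linewidth_hz": float(el.get("linewidth_hz"))}
    elif sid == StepId.WaterFiltering:
        p = {"n_lorentzians": int(el.get("n_lorentzians")), "regions": _regions_of(el)}
    elif sid == StepId.BaselineCorrection:
        p = {"regions": _regions_of(el)}
    elif sid == StepId.ChangePoints:
        p = {"target_points": int(el.get("target_points")), "range": _regions_of(el)[0]}
    elif sid == StepId.SetToZero:
        p = {"intervals": _regions_of(el)}
    elif sid == StepId.Normalization:
        p = {}
    elif sid == StepId.AlignmentCorrection:
        p = {
            "peaks": [float(pk.text) for pk in el.findall("Peak")],
            "noise_range": _regions_of(el, "NoiseRegion")[0],
            "max_shift": int(el.get("max_shift")),
        }
    else:  # OutputRange
        p = {"range": _regions_of(el)[0]}
    return StepRecord(sid, p)


# ---------------------------------------------------------------------------
# voxel <-> element

def _axis_attrs(spec: Spectrum) -> dict:
    vals = spec.axis.values
    diffs = np.diff(vals)
    if not np.allclose(diffs, diffs[0], rtol=1e-9, atol=1e-12 * abs(diffs[0])):
        raise ValidationError("cannot export a non-uniform ppm axis")
    return {
        "points": str(len(spec)),
        "ppm_first": _fmt(vals[0]),
        "ppm_step": _fmt(spec.axis.step),
    }


def _voxel_to_element(vox: VoxelRecord, in_grid: bool) -> etree._Element:
    spec = vox.spectrum
    el = etree.Element("Voxel", **_axis_attrs(spec))
    prm = spec.params
    el.set("transmitter_frequency", _fmt(prm.transmitter_frequency))
    el.set("sweep_width", _fmt(prm.sweep_width))
    el.set("acq_points", str(prm.num_points))
    el.set("reference_ppm", _fmt(prm.reference_ppm))
    el.set("nucleus", prm.nucleus)
    el.set("storage", "complex")
    el.set("label", vox.label)
    if in_grid:
        x, y, z = vox.position
        el.set("Xaxis", str(x))
        el.set("Yaxis", str(y))
        el.set("Zaxis", str(z))
    if vox.snr is not None:
        etree.SubElement(
            el,
            "SNR",
            value=_fmt(vox.snr.snr),
            max_peak=_fmt(vox.snr.max_peak),
            noise_std=_fmt(vox.snr.noise_std),
        )
    data = etree.SubElement(el, "Data")
    interleaved = np.empty(2 * len(spec))
    interleaved[0::2] = spec.intensities.real
    interleaved[1::2] = spec.intensities.imag
    data.text = " ".join(_fmt(v) for v in interleaved)
    return el


def _element_to_voxel(el, in_grid: bool) -> VoxelRecord:
    n = int(el.get("points"))
    params = AcquisitionParams(
        transmitter_frequency=float(el.get("transmitter_frequency")),
        sweep_width=float(el.get("sweep_width")),
        num_points=int(el.get("acq_points")),
        reference_ppm=float(el.get("reference_ppm")),
        nucleus=el.get("nucleus", "1H"),
    )
    axis = PpmAxis.uniform(float(el.get("ppm_first")), float(el.get("ppm_step")), n)
    raw = np.fromiter(map(float, el.findtext("Data", "").split()), dtype=float)
    if el.get("storage") == "complex":
        if len(raw) != 2 * n:
            raise ValidationError(
                f"Voxel Data holds {len(raw)} values, expected {2 * n} (complex storage)"
            )
        intens = raw[0::2] + 1j * raw[1::2]
    else:
        if len(raw) != n:
            raise ValidationError(
                f"Voxel Data holds {len(raw)} values, expected {n} (real storage)"
            )
        intens = raw.astype(complex)
    snr_el = el.find("SNR")
    snr = None
    if snr_el is not None:
        snr = SnrResult(
            snr=float(snr_el.get("value")),
            max_peak=float(snr_el.get("max_peak")),
            noise_std=float(snr_el.get("noise_std")),
        )
    position = None
    if in_grid:
        position = (int(el.get("Xaxis")), int(el.get("Yaxis")), int(el.get("Zaxis")))
    return VoxelRecord(
        spectrum=Spectrum(intens, axis, params),
        label=el.get("label", DEFAULT_LABEL),
        snr=snr,
        position=position,
    )


# ---------------------------------------------------------------------------
# dataset export / import

def export_dataset(ds: Dataset, destination=None) -> etree._ElementTree:
    """Serialize a dataset to exchange XML; write it when given a destination.

    The processing date is auto-assigned (today, ISO-8601) if not already
    set.  Name and Place must be non-empty.
    """
    info = ds.preprocessing.additional_info
    if not info.name.strip() or not info.place.strip():
        raise ValidationError("Name and Place are compulsory for export")
    if info.date is None:
        info.date = _dt.date.today().isoformat()

    root = etree.Element("DATASET")
    prep = etree.SubElement(root, "Preprocessing")
    for step in sorted(ds.preprocessing.steps, key=lambda s: s.step_id):
        prep.append(_step_to_element(step))
    add = etree.SubElement(prep, "AdditionalInformation")
    add.set("include_snr", "true" if info.include_snr else "false")
    etree.SubElement(add, "Name").text = info.name
    etree.SubElement(add, "Place").text = info.place
    etree.SubElement(add, "Date").text = info.date
    etree.SubElement(add, "Label").text = info.label
    kws = etree.SubElement(add, "Keywords")
    for kw in info.keywords:
        etree.SubElement(kws, "Keyword").text = kw
    meta = etree.SubElement(add, "MetaData")
    meta.text = info.meta_data

    if ds.is_grid:
        grid = ds.payload
        grid_el = etree.SubElement(root, "Grid", rows=str(grid.rows), cols=str(grid.cols))
        for row in grid.voxels:
            for vox in row:
                grid_el.append(_voxel_to_element(vox, in_grid=True))
    else:
        root.append(_voxel_to_element(ds.payload, in_grid=False))

    tree = etree.ElementTree(root)
    if not _schema().validate(tree):
        msg = _schema().error_log[0]
        raise ValidationError(f"export produced an invalid document: {msg.message}")
    if destination is not None:
        tree.write(
            str(destination), xml_declaration=True, encoding="UTF-8", pretty_print=False
        )
    return tree


def _parse(source) -> etree._ElementTree:
    if isinstance(source, etree._ElementTree):
        return source
    return etree.parse(str(source))


def _extra_checks(root) -> list:
    """Consistency rules the XSD cannot express."""
    problems = []
    for vox in root.iter("Voxel"):
        n = int(vox.get("points"))
        want = 2 * n if vox.get("storage") == "complex" else n
        got = len(vox.findtext("Data", "").split())
        if got != want:
            problems.append(f"Voxel Data holds {got} values, expected {want}")
    grid = root.find("Grid")
    if grid is not None:
        rows, cols = int(grid.get("rows")), int(grid.get("cols"))
        voxels = grid.findall("Voxel")
        if len(voxels) != rows * cols:
            problems.append(
                f"Grid declares {rows}x{cols}={rows * cols} voxels but holds {len(voxels)}"
            )
        seen = set()
        axes = set()
        for v in voxels:
            pos = (int(v.get("Xaxis", 0)), int(v.get("Yaxis", 0)))
            if not (1 <= pos[0] <= cols and 1 <= pos[1] <= rows):
                problems.append(f"Voxel position {pos} outside {rows}x{cols} grid")
            elif pos in seen:
                problems.append(f"duplicate voxel position {pos}")
            seen.add(pos)
            axes.add((v.get("points"), v.get("ppm_first"), v.get("ppm_step")))
        if len(axes) > 1:
            problems.append("grid voxels do not share an identical ppm axis")
    return problems


def validate(source) -> list:
    """Validate a document against the exchange schema and consistency rules.

    Returns a list of human-readable violations; an empty list means the
    document is valid.  Unreadable input raises ``OSError``.
    """
    try:
        tree = _parse(source)
    except etree.XMLSyntaxError as err:
        return [f"not well-formed XML: {err}"]
    problems = []
    if not _schema().validate(tree):
        problems.extend(
            f"line {e.line}: {e.message}" for e in _schema().error_log
        )
    problems.extend(_extra_checks(tree.getroot()))
    return problems


def read_dataset(source) -> Dataset:
    """Parse an exchange-format document back into a :class:`Dataset`.

    The document is validated first; any schema violation raises
    :class:`~mrsxml.errors.ValidationError` naming the offending element.
    """
    problems = validate(source)
    if problems:
        raise ValidationError(problems[0])
    root = _parse(source).getroot()

    prep = root.find("Preprocessing")
    steps = [
        _element_to_step(el)
        for el in prep
        if el.tag != "AdditionalInformation"
    ]
    add = prep.find("AdditionalInformation")
    info = AdditionalInfo(
        name=add.findtext("Name"),
        place=add.findtext("Place"),
        date=add.findtext("Date"),
        label=add.findtext("Label", DEFAULT_LABEL) or DEFAULT_LABEL,
        keywords=[k.text or "" for k in add.findall("Keywords/Keyword")],
        include_snr=add.get("include_snr", "false") == "true",
        meta_data=add.findtext("MetaData") or "",
    )
    record = PreprocessingRecord(additional_info=info, steps=steps)

    grid_el = root.find("Grid")
    if grid_el is not None:
        rows, cols = int(grid_el.get("rows")), int(grid_el.get("cols"))
        table = [[None] * cols for _ in range(rows)]
        for vel in grid_el.findall("Voxel"):
            vox = _element_to_voxel(vel, in_grid=True)
            x, y, _ = vox.position
            table[y - 1][x - 1] = vox
        payload = GridRecord(table)
    else:
        payload = _element_to_voxel(root.find("Voxel"), in_grid=False)
    return Dataset(preprocessing=record, payload=payload)


# ---------------------------------------------------------------------------
# grid labelling

def set_voxel_label(grid: GridRecord, row: int, col: int, label: str) -> GridRecord:
    """Assign a label to one voxel, addressed in 1-based matrix notation.

    Only the addressed voxel changes; unlabelled voxels keep ``"***"``.
    """
    grid.voxel(row, col).label = label
    return grid


# ---------------------------------------------------------------------------
# config templates

_STEP_TAGS = (
    "SetReference",
    "Apodize",
    "WaterFiltering",
    "BaselineCorrection",
    "ChangePoints",
    "SetToZero",
    "Normalization",
    "AlignmentCorrection",
    "OutputRange",
    "AdditionalInformation",
)


def _opt_range_el(parent, tag, rng) -> None:
    if rng is not None:
        _region_el(parent, tag, rng.upper, rng.lower)


def save_config(cfg: ConfigTemplate, destination=None) -> etree._ElementTree:
    """Write a processing template to XML (lossless round trip)."""
    root = etree.Element("ProcessingTemplate")
    c = cfg

    el = etree.SubElement(root, "SetReference", enabled=str(c.set_reference.enabled).lower())
    el.set("reference_ppm", _fmt(c.set_reference.reference_ppm))

    el = etree.SubElement(root, "Apodize", enabled=str(c.apodize.enabled).lower())
    el.set("shape", c.apodize.shape)
    el.set("linewidth_hz", _fmt(c.apodize.linewidth_hz))

    el = etree.SubElement(root, "WaterFiltering", enabled=str(c.water_filter.enabled).lower())
    el.set("n_lorentzians", str(c.water_filter.n_lorentzians))
    for r in c.water_filter.regions:
        _region_el(el, "Region", r.upper, r.lower)

    el = etree.SubElement(root, "BaselineCorrection", enabled=str(c.baseline.enabled).lower())
    for r in c.baseline.regions:
        _region_el(el, "Region", r.upper, r.lower)

    el = etree.SubElement(root, "ChangePoints", enabled=str(c.change_points.enabled).lower())
    el.set("target_points", str(c.change_points.target_points))
    _opt_range_el(el, "Region", c.change_points.range)

    el = etree.SubElement(root, "SetToZero", enabled=str(c.set_to_zero.enabled).lower())
    for r in c.set_to_zero.intervals:
        _region_el(el, "Region", r.upper, r.lower)

    etree.SubElement(root, "Normalization", enabled=str(c.normalization.enabled).lower())

    el = etree.SubElement(root, "AlignmentCorrection", enabled=str(c.alignment.enabled).lower())
    el.set("brain_1p5T_preset", str(c.alignment.brain_1p5T_preset).lower())
    if c.alignment.preset_peaks_file:
        el.set("preset_peaks_file", c.alignment.preset_peaks_file)
    for p in c.alignment.peaks:
        etree.SubElement(el, "Peak").text = _fmt(p)
    _opt_range_el(el, "NoiseRegion", c.alignment.noise_range)

    el = etree.SubElement(root, "OutputRange", enabled=str(c.output_range.enabled).lower())
    _opt_range_el(el, "Region", c.output_range.range)

    el = etree.SubElement(root, "AdditionalInformation")
    el.set("name", c.additional.name)
    el.set("place", c.additional.place)
    el.set("label", c.additional.label)
    el.set("include_snr", str(c.additional.include_snr).lower())
    for kw in c.additional.keywords:
        etree.SubElement(el, "Keyword").text = kw
    _opt_range_el(el, "SnrNoiseRegion", c.additional.snr_noise_range)

    tree = etree.ElementTree(root)
    if destination is not None:
        tree.write(str(destination), xml_declaration=True, encoding="UTF-8", pretty_print=True)
    return tree


def _bool(el, attr, default=False) -> bool:
    val = el.get(attr)
    if val is None:
        return default
    return val == "true"


def _opt_range(el, tag):
    sub = el.find(tag)
    if sub is None:
        return None
    return PpmRange(upper=float(sub.get("upper")), lower=float(sub.get("lower")))


def _range_list(el, tag="Region"):
    return [PpmRange(upper=float(r.get("upper")), lower=float(r.get("lower"))) for r in el.findall(tag)]


def load_config(source) -> ConfigTemplate:
    """Load a processing template saved by :func:`save_config`."""
    root = _parse(source).getroot()
    if root.tag != "ProcessingTemplate":
        raise ValidationError(f"not a processing template (root <{root.tag}>)")
    for child in root:
        if child.tag not in _STEP_TAGS:
            raise ValidationError(f"unknown step element <{child.tag}> in template")

    def find(tag):
        el = root.find(tag)
        if el is None:
            raise ValidationError(f"template is missing the <{tag}> element")
        return el

    sr = find("SetReference")
    ap = find("Apodize")
    wf = find("WaterFiltering")
    bl = find("BaselineCorrection")
    cp = find("ChangePoints")
    sz = find("SetToZero")
    nm = find("Normalization")
    al = find("AlignmentCorrection")
    orr = find("OutputRange")
    ad = find("AdditionalInformation")

    return ConfigTemplate(
        set_reference=SetReferenceConfig(
            enabled=_bool(sr, "enabled"), reference_ppm=float(sr.get("reference_ppm"))
        ),
        apodize=ApodizeConfig(
            enabled=_bool(ap, "enabled"),
            shape=ap.get("shape"),
            linewidth_hz=float(ap.get("linewidth_hz")),
        ),
        water_filter=WaterFilterConfig(
            enabled=_bool(wf, "enabled"),
            n_lorentzians=int(wf.get("n_lorentzians")),
            regions=_range_list(wf),
        ),
        baseline=BaselineConfig(enabled=_bool(bl, "enabled"), regions=_range_list(bl)),
        change_points=ChangePointsConfig(
            enabled=_bool(cp, "enabled"),
            target_points=int(cp.get("target_points")),
            range=_opt_range(cp, "Region"),
        ),
        set_to_zero=SetToZeroConfig(enabled=_bool(sz, "enabled"), intervals=_range_list(sz)),
        normalization=NormalizationConfig(enabled=_bool(nm, "enabled")),
        alignment=AlignmentConfig(
            enabled=_bool(al, "enabled"),
            peaks=[float(p.text) for p in al.findall("Peak")],
            noise_range=_opt_range(al, "NoiseRegion"),
            brain_1p5T_preset=_bool(al, "brain_1p5T_preset"),
            preset_peaks_file=al.get("preset_peaks_file"),
        ),
        output_range=OutputRangeConfig(
            enabled=_bool(orr, "enabled"), range=_opt_range(orr, "Region")
        ),
        additional=AdditionalConfig(
            name=ad.get("name", ""),
            place=ad.get("place", ""),
            label=ad.get("label", DEFAULT_LABEL),
            keywords=[k.text or "" for k in ad.findall("Keyword")],
            include_snr=_bool(ad, "include_snr"),
            snr_noise_range=_opt_range(ad, "SnrNoiseRegion"),
        ),
    )


# ---------------------------------------------------------------------------
# flat-array parity export

def write_canonical_ascii(payload, destination) -> None:
    """Write a spectrum as flat space-separated real intensities.

    This is the layout used by the canonical multi-centre pattern-recognition
    format: one line of space-separated values, the first value at the
    highest ppm (7.1 ppm after the canonical pipeline).  Only the real part
    is written — the canonical files are real-valued.
    """
    if isinstance(payload, Dataset):
        payload = payload.payload
    if isinstance(payload, VoxelRecord):
        payload = payload.spectrum
    if not isinstance(payload, Spectrum):
        raise ParameterError("canonical ASCII export needs a single spectrum")
    with open(str(destination), "w") as fh:
        fh.write(" ".join(_fmt(v) for v in payload.intensities.real))
        fh.write("\n")
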