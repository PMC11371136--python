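"""File formats: RSML root traces, minimal VCF genotypes, CSV tables.

RSML (Root System Markup Language) is the XML interchange format
exported by root tracers such as SmartRoot.  A time-lapse series is
written as one ``<scene>`` per time point, each holding one plant with
one root whose geometry is a polyline of ``<point x= y=/>`` nodes.
Coordinates are stored in the unit named in the metadata (cm here);
readers convert using the file's ``unit``/``resolution`` metadata or an
explicit scale override.

The VCF dialect is deliberately minimal: biallelic sites, a GT
subfield, ``./.`` for missing, 1-based positions.  Multi-allelic
records are skipped with a logged count.
"""

from __future__ import annotations

import logging
from pathlib import Path
from xml.etree import ElementTree as ET

import numpy as np
import pandas as pd

from .simgen import GenotypePanel
from .traits import RootPolyline, RootTimeSeries

logger = logging.getLogger(__name__)

__all__ = [
    "write_rsml", "read_rsml",
    "write_long_csv", "read_long_csv",
    "write_vcf", "read_vcf",
    "write_dosage_csv", "read_dosage_csv",
    "read_genotypes",
]

_UNIT_TO_CM = {"cm": 1.0, "mm": 0.1, "m": 100.0, "inch": 2.54}


def write_rsml(series_list: list[RootTimeSeries], path: str | Path) -> None:
    """Write time series as RSML 1.0, one scene per time point."""
    root = ET.Element("rsml")
    meta = ET.SubElement(root, "metadata")
    ET.SubElement(meta, "version").text = "1"
    ET.SubElement(meta, "unit").text = "cm"
    ET.SubElement(meta, "resolution").text = "1"
    ET.SubElement(meta, "software").text = "sita"
    for series in series_list:
        for poly in series.polylines:
            scene = ET.SubElement(root, "scene")
            scene.set("label", f"{poly.time_h:.10g}")
            plant = ET.SubElement(scene, "plant")
            plant.set("id", poly.plant_id)
            plant.set("label", series.treatment)
            r = ET.SubElement(plant, "root")
            r.set("id", f"{poly.plant_id}.1")
            geom = ET.SubElement(r, "geometry")
            pl = ET.SubElement(geom, "polyline")
            for x, y in poly.points:
                pt = ET.SubElement(pl, "point")
                pt.set("x", f"{x:.12g}")
                pt.set("y", f"{y:.12g}")
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, encoding="unicode", xml_declaration=True)


def read_rsml(path: str | Path,
              scale_to_cm: float | None = None) -> list[RootTimeSeries]:
    """Read RSML written by :func:`write_rsml` (or compatible exports).

    ``scale_to_cm`` overrides the file's unit metadata; required when the
    file declares no unit.  Raises ``ValueError`` with the offending node
    path on malformed geometry.
    """
    try:
        tree = ET.parse(path)
    except ET.ParseError as err:
        raise ValueError(f"malformed RSML XML in {path}: {err}") from err
    root = tree.getroot()
    if scale_to_cm is None:
        unit_el = root.find("./metadata/unit")
        unit = unit_el.text.strip().lower() if unit_el is not None and unit_el.text else None
        if unit is None:
            raise ValueError(f"{path}: no unit metadata; pass scale_to_cm")
        if unit not in _UNIT_TO_CM:
            raise ValueError(f"{path}: unknown unit {unit!r}; pass scale_to_cm")
        res_el = root.find("./metadata/resolution")
        res = float(res_el.text) if res_el is not None and res_el.text else 1.0
        scale_to_cm = _UNIT_TO_CM[unit] / res

    frames: dict[str, list[tuple[float, str, np.ndarray]]] = {}
    for si, scene in enumerate(root.iter("scene")):
        time_h = float(scene.get("label", si))
        for plant in scene.iter("plant"):
            pid = plant.get("id", "plant")
            treatment = plant.get("label", "control")
            for ri, r in enumerate(plant.iter("root")):
                pts = []
                for pi, pt in enumerate(r.iter("point")):
                    loc = f"scene[{si}]/plant[{pid}]/root[{ri}]/point[{pi}]"
                    try:
                        pts.append((float(pt.get("x")), float(pt.get("y"))))
                    except (TypeError, ValueError) as err:
                        raise ValueError(
                            f"{path}: corrupted point node at {loc}") from err
                if not pts:
                    raise ValueError(
                        f"{path}: missing geometry at scene[{si}]/plant[{pid}]")
                arr = np.asarray(pts, dtype=float) * scale_to_cm
                frames.setdefault(pid, []).append((time_h, treatment, arr))

    out = []
    for pid, items in frames.items():
        items.sort(key=lambda it: it[0])
        polys = [RootPolyline(arr, plant_id=pid, time_h=t)
                 for t, _, arr in items]
        out.append(RootTimeSeries(polys, treatment=items[0][1]))
    return out


def write_long_csv(series_list: list[RootTimeSeries], path: str | Path) -> None:
    """Long-format trace CSV: one row per polyline point per frame."""
    rows = []
    for series in series_list:
        for fi, poly in enumerate(series.polylines):
            for pi, (x, y) in enumerate(poly.points):
                rows.append((poly.plant_id, series.treatment, fi,
                             poly.time_h, pi, x, y))
    df = pd.DataFrame(rows, columns=["plant_id", "treatment", "frame",
                                     "time_h", "point_index", "x_cm", "y_cm"])
    df.to_csv(path, index=False)


def read_long_csv(path: str | Path) -> list[RootTimeSeries]:
    df = pd.read_csv(path)
    out = []
    for pid, g in df.groupby("plant_id", sort=False):
        polys = []
        treatment = str(g["treatment"].iloc[0])
        for _, f in g.groupby("frame", sort=True):
            f = f.sort_values("point_index")
            polys.append(RootPolyline(f[["x_cm", "y_cm"]].to_numpy(float),
                                      plant_id=str(pid),
                                      time_h=float(f["time_h"].iloc[0])))
        out.append(RootTimeSeries(polys, treatment=treatment))
    return out


def write_vcf(panel: GenotypePanel, path: str | Path) -> None:
    """Minimal biallelic VCF with a GT-only FORMAT field."""
    gt_of = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=sita\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(panel.accession_ids) + "\n")
        for j, mk in panel.markers.iterrows():
            calls = [gt_of.get(v, "./.") if np.isfinite(v) else "./."
                     for v in panel.dosages[:, j]]
            fh.write(f"{mk['chrom']}\t{mk['pos']}\t{mk['id']}\t{mk['ref']}\t"
                     f"{mk['alt']}\t.\t.\t.\tGT\t" + "\t".join(calls) + "\n")


def read_vcf(path: str | Path) -> GenotypePanel:
    """Read a minimal biallelic VCF into a dosage panel.

    Multi-allelic records are skipped with a logged count; ``./.`` (or
    any call with a missing allele) becomes a missing dosage.
    """
    samples: list[str] = []
    rows, meta = [], []
    n_multi = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                fields = line.split("\t")
                if len(fields) < 10:
                    raise ValueError(f"{path}: header lists no samples")
                samples = fields[9:]
                continue
            if not samples:
                raise ValueError(f"{path}: data before #CHROM header")
            fields = line.split("\t")
            if len(fields) != 9 + len(samples):
                raise ValueError(f"{path}: sample column count mismatch on "
                                 f"line {fields[:3]}")
            chrom, pos, vid, ref, alt = fields[:5]
            if "," in alt:
                n_multi += 1
                continue
            fmt = fields[8].split(":")
            try:
                gt_i = fmt.index("GT")
            except ValueError:
                raise ValueError(f"{path}: record without GT field")
            dos = []
            for call in fields[9:]:
                gt = call.split(":")[gt_i].replace("|", "/")
                alleles = gt.split("/")
                if "." in alleles:
                    dos.append(np.nan)
                else:
                    dos.append(float(sum(int(a) for a in alleles)))
            rows.append(dos)
            meta.append((chrom, int(pos), vid, ref, alt))
    if not rows:
        raise ValueError(f"{path}: no usable variant records")
    if n_multi:
        logger.info("skipped %d multi-allelic record(s) in %s", n_multi, path)
    markers = pd.DataFrame(meta, columns=["chrom", "pos", "id", "ref", "alt"])
    return GenotypePanel(np.asarray(rows, dtype=float).T, samples, markers)


def write_dosage_csv(panel: GenotypePanel, path: str | Path,
                     markers_path: str | Path | None = None) -> None:
    """Dosage matrix CSV (rows = accessions) plus a marker sidecar CSV."""
    df = pd.DataFrame(panel.dosages, index=panel.accession_ids,
                      columns=panel.markers["id"])
    df.index.name = "accession_id"
    df.to_csv(path)
    if markers_path is not None:
        panel.markers.to_csv(markers_path, index=False)


def read_dosage_csv(path: str | Path,
                    markers_path: str | Path | None = None) -> GenotypePanel:
    df = pd.read_csv(path, index_col=0)
    if markers_path is not None:
        markers = pd.read_csv(markers_path)
    else:
        markers = pd.DataFrame({"chrom": "1",
                                "pos": np.arange(1, df.shape[1] + 1),
                                "id": df.columns,
                                "ref": "A", "alt": "T"})
    return GenotypePanel(df.to_numpy(dtype=float),
                         [str(i) for i in df.index], markers)


def read_genotypes(path: str | Path, format: str | None = None,
                   markers_path: str | Path | None = None) -> GenotypePanel:
    """Read a genotype panel, dispatching on format ('vcf' or 'csv')."""
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix.lower() == ".vcf" else "csv"
    if format == "vcf":
        return read_vcf(path)
    if format == "csv":
        return read_dosage_csv(path, markers_path)
    raise ValueError(f"unknown genotype format {format!r}")
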