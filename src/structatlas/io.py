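"""Readers and writers for every on-disk format the toolkit touches.

JSON dialects (structural graphs, nomenclatures, transform and cohort
manifests) use sorted keys and Python's shortest round-trip float
representation, so a given in-memory object always serializes to the same
bytes.  Volumes and deformation fields are NIfTI-1 (read through nibabel;
the qform/sform provides the voxel→world map and files with neither are
rejected rather than silently defaulted).  Meshes are Wavefront OBJ
(through trimesh) or GIFTI (through nibabel); per-vertex textures are GIFTI
functional files or CSV.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import nibabel as nib
import numpy as np
import pandas as pd
import trimesh as _trimesh

from .cohort import Cohort
from .core_model import (
    StructureEdge,
    StructureNode,
    StructuralGraph,
    TriangleMesh,
    VolumeGeometry,
    VoxelSurfaceSet,
)
from .errors import MissingFile, ParseError, UnsupportedVersion
from .morphometry import MorphometryTable
from .nomenclature import Nomenclature, NomenclatureEntry
from .transform_graph import (
    AffineTransform,
    DeformationFieldTransform,
    TransformationGraph,
)
from .fusion_sampling import VertexTexture

FORMAT_VERSION = "1.0"

PathLike = Union[str, Path]


def _check_version(doc: dict, path: PathLike, expected_format: str):
    if doc.get("format") != expected_format:
        raise ParseError(
            f"{path}: expected format {expected_format!r}, got {doc.get('format')!r}"
        )
    version = str(doc.get("version", ""))
    try:
        major = int(version.split(".")[0])
    except (ValueError, IndexError):
        raise ParseError(f"{path}: malformed version {version!r}") from None
    if major > int(FORMAT_VERSION.split(".")[0]):
        raise UnsupportedVersion(f"{path}: version {version} newer than {FORMAT_VERSION}")


def _load_json(path: PathLike, expected_format: str) -> dict:
    try:
        with open(path) as f:
            doc = json.load(f)
    except FileNotFoundError:
        raise MissingFile(f"no such file: {path}") from None
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: line {exc.lineno}, col {exc.colno}: {exc.msg}") from None
    if not isinstance(doc, dict):
        raise ParseError(f"{path}: top level must be a JSON object")
    _check_version(doc, path, expected_format)
    return doc


def _dump_json(doc: dict, path: PathLike):
    with open(path, "w") as f:
        json.dump(doc, f, sort_keys=True, indent=1)
        f.write("\n")


# ---------------------------------------------------------------------------
# structural graphs (.sgraph.json)
# ---------------------------------------------------------------------------

def _mesh_to_doc(mesh: Optional[TriangleMesh]):
    if mesh is None:
        return None
    return {
        "vertices": mesh.vertices.tolist(),
        "triangles": mesh.triangles.tolist(),
    }


def _mesh_from_doc(doc, path):
    if doc is None:
        return None
    try:
        return TriangleMesh(doc["vertices"], doc["triangles"])
    except (KeyError, ValueError) as exc:
        raise ParseError(f"{path}: bad mesh: {exc}") from None


def write_graph(graph: StructuralGraph, path: PathLike) -> Path:
    """Serialize a structural graph to the .sgraph.json dialect.

    Voxel sets are stored as sorted index triples, keys are sorted and
    floats use the shortest exact representation: identical graphs always
    produce identical bytes.
    """
    geom = graph.geometry
    doc = {
        "format": "sgraph_json",
        "version": FORMAT_VERSION,
        "subject_id": graph.subject_id,
        "hemisphere": graph.hemisphere.value,
        "referential_id": graph.referential_id,
        "metadata": dict(graph.metadata),
        "geometry": None
        if geom is None
        else {
            "shape": list(geom.shape),
            "voxel_size": list(geom.voxel_size),
            "voxel_to_world": geom.voxel_to_world.tolist(),
        },
        "nodes": [
            {
                "node_id": node.node_id,
                "label": node.label,
                "properties": dict(node.properties),
                "voxels": None
                if node.voxel_rep is None
                else node.voxel_rep.array.tolist(),
                "mesh": _mesh_to_doc(node.mesh),
            }
            for _, node in sorted(graph.nodes.items())
        ],
        "edges": [
            {
                "edge_id": edge.edge_id,
                "kind": edge.kind.value,
                "endpoints": list(edge.endpoints),
                "properties": dict(edge.properties),
            }
            for _, edge in sorted(graph.edges.items())
        ],
    }
    _dump_json(doc, path)
    return Path(path)


def read_graph(path: PathLike) -> StructuralGraph:
    """Read a .sgraph.json structural graph."""
    doc = _load_json(path, "sgraph_json")
    try:
        graph = StructuralGraph(
            doc["subject_id"],
            doc["hemisphere"],
            doc["referential_id"],
            doc.get("metadata", {}),
        )
        geom_doc = doc.get("geometry")
        geom = (
            None
            if geom_doc is None
            else VolumeGeometry(
                geom_doc["shape"], geom_doc["voxel_size"], geom_doc["voxel_to_world"]
            )
        )
        for ndoc in doc["nodes"]:
            voxels = ndoc.get("voxels")
            if voxels is not None and geom is None:
                raise ParseError(f"{path}: node has voxels but file lacks geometry")
            graph.add_node(
                StructureNode(
                    ndoc["node_id"],
                    ndoc.get("label", "unknown"),
                    None if voxels is None else VoxelSurfaceSet(voxels, geom),
                    _mesh_from_doc(ndoc.get("mesh"), path),
                    dict(ndoc.get("properties", {})),
                )
            )
        for edoc in doc["edges"]:
            graph.add_edge(
                StructureEdge(
                    edoc["edge_id"],
                    edoc["kind"],
                    tuple(edoc["endpoints"]),
                    dict(edoc.get("properties", {})),
                )
            )
    except ParseError:
        raise
    except (KeyError, TypeError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from None
    return graph


# ---------------------------------------------------------------------------
# nomenclatures (.nom.json)
# ---------------------------------------------------------------------------

def _entry_to_doc(entry: NomenclatureEntry) -> dict:
    doc: dict = {"name": entry.name, "children": [_entry_to_doc(c) for c in entry.children]}
    if entry.color is not None:
        doc["color"] = list(entry.color)
    return doc


def _entry_from_doc(doc: dict, path) -> NomenclatureEntry:
    try:
        return NomenclatureEntry(
            doc["name"],
            tuple(doc["color"]) if "color" in doc else None,
            [_entry_from_doc(c, path) for c in doc.get("children", [])],
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ParseError(f"{path}: bad nomenclature entry: {exc}") from None


def write_nomenclature(nom: Nomenclature, path: PathLike) -> Path:
    doc = {
        "format": "nom_json",
        "version": FORMAT_VERSION,
        "nomenclature_version": nom.version,
        "tree": _entry_to_doc(nom.root),
    }
    _dump_json(doc, path)
    return Path(path)


def read_nomenclature(path: PathLike) -> Nomenclature:
    doc = _load_json(path, "nom_json")
    root = _entry_from_doc(doc.get("tree", {}), path)
    try:
        return Nomenclature(root, doc.get("nomenclature_version", "1.0"))
    except ValueError as exc:  # duplicate names
        raise ParseError(f"{path}: {exc}") from None


# ---------------------------------------------------------------------------
# affine transforms (plain text 4x4) and transform manifests
# ---------------------------------------------------------------------------

def write_affine(matrix: np.ndarray, path: PathLike) -> Path:
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (4, 4):
        raise ValueError("affine must be 4x4")
    with open(path, "w") as f:
        for row in matrix:
            f.write(" ".join(repr(float(v)) for v in row) + "\n")
    return Path(path)


def read_affine(path: PathLike) -> np.ndarray:
    try:
        matrix = np.loadtxt(path, dtype=float)
    except FileNotFoundError:
        raise MissingFile(f"no such file: {path}") from None
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from None
    if matrix.shape != (4, 4):
        raise ParseError(f"{path}: expected 4 lines of 4 numbers, got shape {matrix.shape}")
    return matrix


def write_transform_manifest(records: list[dict], path: PathLike) -> Path:
    """Write a transform-graph manifest: records of
    ``{source, target, file, kind}`` (+ optional ``convention`` for fields)."""
    doc = {
        "format": "transform_manifest_json",
        "version": FORMAT_VERSION,
        "transforms": sorted(
            records, key=lambda r: (r["source"], r["target"], r["file"])
        ),
    }
    _dump_json(doc, path)
    return Path(path)


def read_transform_manifest(
    path: PathLike, tg: Optional[TransformationGraph] = None
) -> TransformationGraph:
    """Load a transform manifest into a transformation graph.

    Files are resolved relative to the manifest; a dangling reference
    raises :class:`MissingFile` naming the missing path.  Deformation-field
    records may declare ``convention: displacement`` to be converted to
    absolute target coordinates on load.
    """
    doc = _load_json(path, "transform_manifest_json")
    base = Path(path).parent
    tg = tg or TransformationGraph()
    for rec in doc.get("transforms", []):
        try:
            source, target, kind = rec["source"], rec["target"], rec["kind"]
            file = base / rec["file"]
        except (KeyError, TypeError) as exc:
            raise ParseError(f"{path}: bad transform record: {exc}") from None
        if not file.exists():
            raise MissingFile(f"{path}: referenced file does not exist: {file}")
        if kind == "affine":
            tg.add_affine(AffineTransform(source, target, read_affine(file)))
        elif kind == "field":
            field, geom = read_deformation_field(file)
            if rec.get("convention", "absolute") == "displacement":
                tg.add_field(
                    DeformationFieldTransform.from_displacements(source, target, field, geom)
                )
            else:
                tg.add_field(DeformationFieldTransform(source, target, field, geom))
        else:
            raise ParseError(f"{path}: unknown transform kind {kind!r}")
    return tg


# ---------------------------------------------------------------------------
# NIfTI volumes and deformation fields
# ---------------------------------------------------------------------------

def _nifti_geometry(img, path) -> VolumeGeometry:
    header = img.header
    if int(header["sform_code"]) > 0:
        affine = img.get_sform()
    elif int(header["qform_code"]) > 0:
        affine = img.get_qform()
    else:
        raise ParseError(f"{path}: neither qform nor sform set; orientation ambiguous")
    shape = img.shape[:3]
    voxel_size = tuple(float(z) for z in header.get_zooms()[:3])
    return VolumeGeometry(shape, voxel_size, affine)


def read_volume(path: PathLike) -> tuple[np.ndarray, VolumeGeometry]:
    """Read a NIfTI scalar volume and its sampling geometry."""
    try:
        img = nib.load(str(path))
    except FileNotFoundError:
        raise MissingFile(f"no such file: {path}") from None
    return np.asarray(img.dataobj, dtype=float), _nifti_geometry(img, path)


def write_volume(data: np.ndarray, geometry: VolumeGeometry, path: PathLike) -> Path:
    img = nib.Nifti1Image(np.asarray(data), geometry.voxel_to_world)
    img.header.set_zooms(geometry.voxel_size + (1.0,) * (data.ndim - 3))
    img.set_sform(geometry.voxel_to_world, code=2)
    img.set_qform(None)
    nib.save(img, str(path))
    return Path(path)


def read_deformation_field(path: PathLike) -> tuple[np.ndarray, VolumeGeometry]:
    """Read a 3-component vector volume (4D NIfTI with last axis 3)."""
    data, geom = read_volume(path)
    if data.ndim == 5 and data.shape[3] == 1:  # NIfTI vector convention
        data = data[:, :, :, 0, :]
    if data.ndim != 4 or data.shape[-1] != 3:
        raise ParseError(f"{path}: expected a 3-component vector volume, got {data.shape}")
    return data, geom


def write_deformation_field(
    field: np.ndarray, geometry: VolumeGeometry, path: PathLike
) -> Path:
    field = np.asarray(field, dtype=float)
    if field.ndim != 4 or field.shape[-1] != 3:
        raise ValueError(f"field must have shape (nx, ny, nz, 3), got {field.shape}")
    return write_volume(field, geometry, path)


# ---------------------------------------------------------------------------
# meshes (OBJ, GIFTI) and textures
# ---------------------------------------------------------------------------

def read_mesh(path: PathLike) -> TriangleMesh:
    """Read a triangle mesh from OBJ or GIFTI, by extension."""
    path = Path(path)
    if not path.exists():
        raise MissingFile(f"no such file: {path}")
    if path.suffix.lower() == ".obj":
        loaded = _trimesh.load(str(path), file_type="obj", process=False)
        return TriangleMesh(np.asarray(loaded.vertices), np.asarray(loaded.faces))
    if path.suffix.lower() == ".gii":
        img = nib.load(str(path))
        pts = img.get_arrays_from_intent("NIFTI_INTENT_POINTSET")
        tris = img.get_arrays_from_intent("NIFTI_INTENT_TRIANGLE")
        if not pts or not tris:
            raise ParseError(f"{path}: GIFTI file lacks pointset/triangle arrays")
        return TriangleMesh(pts[0].data, tris[0].data)
    raise ParseError(f"{path}: unsupported mesh extension {path.suffix!r}")


def write_mesh(mesh: TriangleMesh, path: PathLike) -> Path:
    path = Path(path)
    if path.suffix.lower() == ".obj":
        tm = _trimesh.Trimesh(mesh.vertices, mesh.triangles, process=False)
        tm.export(str(path), file_type="obj")
    elif path.suffix.lower() == ".gii":
        img = nib.gifti.GiftiImage(
            darrays=[
                nib.gifti.GiftiDataArray(
                    mesh.vertices.astype(np.float32), intent="NIFTI_INTENT_POINTSET"
                ),
                nib.gifti.GiftiDataArray(
                    mesh.triangles.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE"
                ),
            ]
        )
        nib.save(img, str(path))
    else:
        raise ValueError(f"unsupported mesh extension {path.suffix!r}")
    return path


def write_texture(texture: VertexTexture, path: PathLike) -> Path:
    """Write per-vertex values as a GIFTI functional file (.gii) or CSV."""
    path = Path(path)
    if path.suffix.lower() == ".gii":
        img = nib.gifti.GiftiImage(
            darrays=[
                nib.gifti.GiftiDataArray(
                    texture.values.astype(np.float32), intent="NIFTI_INTENT_NONE"
                )
            ]
        )
        nib.save(img, str(path))
    else:
        pd.DataFrame({"value": texture.values}).to_csv(path, index_label="vertex")
    return path


def read_texture(path: PathLike) -> VertexTexture:
    path = Path(path)
    if not path.exists():
        raise MissingFile(f"no such file: {path}")
    if path.suffix.lower() == ".gii":
        img = nib.load(str(path))
        return VertexTexture(img.darrays[0].data)
    return VertexTexture(pd.read_csv(path)["value"].to_numpy())


# ---------------------------------------------------------------------------
# cohorts and morphometry tables
# ---------------------------------------------------------------------------

def write_cohort(cohort: Cohort, directory: PathLike) -> Path:
    """Write a cohort: one .sgraph.json per subject, optional affine files,
    the shared nomenclature, and a manifest listing them all."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    subjects = []
    for subject_id in sorted(cohort.subjects):
        graph_file = f"{subject_id}.sgraph.json"
        write_graph(cohort.subjects[subject_id], directory / graph_file)
        record = {"subject_id": subject_id, "graph": graph_file}
        if subject_id in cohort.to_common:
            t = cohort.to_common[subject_id]
            affine_file = f"{subject_id}.to_common.trm"
            write_affine(t.matrix, directory / affine_file)
            record["to_common"] = affine_file
            record["common_referential"] = t.target
        subjects.append(record)
    doc = {
        "format": "cohort_manifest_json",
        "version": FORMAT_VERSION,
        "subjects": subjects,
    }
    if cohort.shared_nomenclature is not None:
        write_nomenclature(cohort.shared_nomenclature, directory / "nomenclature.nom.json")
        doc["nomenclature"] = "nomenclature.nom.json"
    _dump_json(doc, directory / "cohort.json")
    return directory / "cohort.json"


def read_cohort(manifest_path: PathLike) -> Cohort:
    doc = _load_json(manifest_path, "cohort_manifest_json")
    base = Path(manifest_path).parent
    nom = None
    if "nomenclature" in doc:
        nom = read_nomenclature(base / doc["nomenclature"])
    cohort = Cohort(shared_nomenclature=nom)
    for rec in doc.get("subjects", []):
        graph_file = base / rec["graph"]
        if not graph_file.exists():
            raise MissingFile(f"{manifest_path}: missing graph file {graph_file}")
        graph = read_graph(graph_file)
        to_common = None
        if "to_common" in rec:
            affine_file = base / rec["to_common"]
            if not affine_file.exists():
                raise MissingFile(f"{manifest_path}: missing affine file {affine_file}")
            to_common = AffineTransform(
                graph.referential_id,
                rec.get("common_referential", "common"),
                read_affine(affine_file),
            )
        cohort.add_subject(graph, to_common)
    return cohort


def write_morphometry_csv(table: MorphometryTable, path: PathLike) -> Path:
    frame = table.to_frame()
    # shortest exact float representation: round-trip-safe CSV values
    frame["value"] = frame["value"].map(lambda v: repr(float(v)))
    frame.to_csv(path, index=False)
    return Path(path)


def read_morphometry_csv(path: PathLike) -> MorphometryTable:
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except FileNotFoundError:
        raise MissingFile(f"no such file: {path}") from None
    expected = list(MorphometryTable.COLUMNS)
    if list(frame.columns) != expected:
        raise ParseError(f"{path}: expected columns {expected}, got {list(frame.columns)}")
    return MorphometryTable(frame.itertuples(index=False, name=None))
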