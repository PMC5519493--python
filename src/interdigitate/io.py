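"""Study container and surface-format I/O.

The study container is a single HDF5 file::

    /mesh/{vertices,faces,hemisphere,zone_label}   + attr level
    /subjects/<id>/template/{assignment,zone_label} + attrs
    /subjects/<id>/sessions/<id>/data              (vertex x time)
    /subjects/<id>/sessions/<id>/nuisance          + attr columns

GIFTI export (via nibabel) and CSV export of templates, QC maps and FC
maps are provided for interoperability with standard surface tooling.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .mesh import SurfaceMesh
from .simulate import GeneratorParams, SessionTimeseries, StudyDataset
from .templates import NetworkTemplate


def save_study(path, study: StudyDataset) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["params"] = json.dumps(
            {k: v for k, v in vars(study.params).items()}, default=str
        )
        g = f.create_group("mesh")
        g.create_dataset("vertices", data=study.mesh.vertices)
        g.create_dataset("faces", data=study.mesh.faces)
        g.create_dataset("hemisphere",
                         data=(study.mesh.hemisphere == "R").astype(np.int8))
        g.create_dataset("zone_label", data=study.mesh.zone_label)
        g.attrs["level"] = study.mesh.level
        subs = f.create_group("subjects")
        for s, tpl in study.templates.items():
            gs = subs.create_group(str(s))
            gt = gs.create_group("template")
            gt.create_dataset("assignment", data=tpl.assignment)
            gt.create_dataset("zone_label", data=tpl.zone_label)
            gt.attrs["n_networks"] = tpl.n_networks
            gt.attrs["zones"] = tpl.zones
            gt.attrs["anchors"] = json.dumps(
                {str(z): {str(n): int(v) for n, v in d.items()}
                 for z, d in tpl.anchors.items()}
            )
            gr = gs.create_group("sessions")
            for r in study.run_ids(s):
                ts = study.sessions[(s, r)]
                grun = gr.create_group(str(r))
                grun.create_dataset("data", data=ts.data)
                grun.create_dataset("nuisance", data=ts.nuisance.to_numpy())
                grun.attrs["nuisance_columns"] = list(map(str, ts.nuisance.columns))
                grun.attrs["tr_seconds"] = ts.tr_seconds
                if ts.rng_seed is not None:
                    grun.attrs["rng_seed"] = ts.rng_seed


def load_study(path) -> StudyDataset:
    with h5py.File(path, "r") as f:
        g = f["mesh"]
        hemi = np.where(np.asarray(g["hemisphere"]) == 1, "R", "L")
        mesh = SurfaceMesh(
            vertices=np.asarray(g["vertices"]), faces=np.asarray(g["faces"]),
            hemisphere=hemi, zone_label=np.asarray(g["zone_label"]),
            level=int(g.attrs["level"]),
        )
        raw = json.loads(f.attrs["params"])
        fields = set(GeneratorParams.__dataclass_fields__)
        kwargs = {}
        for k, v in raw.items():
            if k in fields and v is not None:
                if v == "None":
                    v = None
                kwargs[k] = v
        params = GeneratorParams(**kwargs)
        templates, sessions = {}, {}
        for sid, gs in f["subjects"].items():
            s = int(sid)
            gt = gs["template"]
            anchors = {int(z): {int(n): v for n, v in d.items()}
                       for z, d in json.loads(gt.attrs["anchors"]).items()}
            templates[s] = NetworkTemplate(
                assignment=np.asarray(gt["assignment"]),
                n_networks=int(gt.attrs["n_networks"]),
                zones=list(gt.attrs["zones"]),
                zone_label=np.asarray(gt["zone_label"]),
                anchors=anchors,
            )
            for rid, grun in gs["sessions"].items():
                r = int(rid)
                nuis = pd.DataFrame(np.asarray(grun["nuisance"]),
                                    columns=list(grun.attrs["nuisance_columns"]))
                sessions[(s, r)] = SessionTimeseries(
                    data=np.asarray(grun["data"]),
                    tr_seconds=float(grun.attrs["tr_seconds"]),
                    nuisance=nuis, run_id=r, subject_id=s,
                    rng_seed=int(grun.attrs["rng_seed"]) if "rng_seed" in grun.attrs else None,
                )
    study = StudyDataset(mesh=mesh, params=params, templates=templates)
    study.sessions = sessions
    return study


def save_z_matrix(path, z, dtype=np.float32) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("z", data=z.z.astype(dtype))
        d.attrs["n_runs"] = z.n_runs_averaged
        d.attrs["label"] = z.dataset_label
        if z.mask is not None:
            f.create_dataset("mask", data=z.mask)


def template_to_csv(path, template: NetworkTemplate) -> None:
    pd.DataFrame({"vertex": np.arange(len(template.assignment)),
                  "network": template.assignment}).to_csv(path, index=False)


def map_to_csv(path, values: np.ndarray, name: str = "value") -> None:
    pd.DataFrame({"vertex": np.arange(len(values)), name: values}).to_csv(
        path, index=False)


def mesh_to_gifti(path, mesh: SurfaceMesh, hemisphere: str = "L") -> None:
    """Write one hemisphere as a .surf.gii surface."""
    import nibabel as nib

    sel = mesh.hemisphere == hemisphere
    idx = np.flatnonzero(sel)
    remap = {int(v): i for i, v in enumerate(idx)}
    face_sel = np.all(np.isin(mesh.faces, idx), axis=1)
    faces = np.vectorize(remap.get)(mesh.faces[face_sel])
    img = nib.gifti.GiftiImage(darrays=[
        nib.gifti.GiftiDataArray(mesh.vertices[sel].astype(np.float32),
                                 intent="NIFTI_INTENT_POINTSET"),
        nib.gifti.GiftiDataArray(faces.astype(np.int32),
                                 intent="NIFTI_INTENT_TRIANGLE"),
    ])
    nib.save(img, str(path))


def map_to_gifti(path, values: np.ndarray) -> None:
    """Write a per-vertex scalar map as a .func.gii."""
    import nibabel as nib

    img = nib.gifti.GiftiImage(darrays=[
        nib.gifti.GiftiDataArray(np.asarray(values, dtype=np.float32),
                                 intent="NIFTI_INTENT_NONE"),
    ])
    nib.save(img, str(path))


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
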