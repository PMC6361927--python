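# vimloc

Localization and automated segmentation analysis of the **ventro-intermediate
(Vim) thalamic nucleus**, the standard surgical target for drug-resistant
tremor (deep brain stimulation, radiofrequency or radiosurgical thalamotomy,
focused ultrasound).

The Vim is invisible on routine clinical MRI, so it is targeted indirectly —
classically with the *quadrilatere of Guiot*, a geometric construction on
stereotactic landmarks (AC, PC, third-ventricle lateral wall) that places the
target 11 mm lateral to the ventricle wall. At 7T, susceptibility-weighted
imaging (SWI) renders the Vim as a hyperintense band between the darker Vc
and Vo nuclei, making direct delineation possible. `vimloc` provides the
analysis machinery to compare such a directly delineated Vim against:

1. the **Guiot target point** and its targeting reproducibility,
2. the diffusion-parcellation **motor-nuclei (VLV) cluster** that encloses
   the Vim, via an eight-way geometric subdivision of ROIs
   (superior/inferior × anterior/lateral/posterior/ventral) and
   containment/adjacency/centroid relations,
3. a **multi-atlas segmentation**: decile-landmark intensity
   standardization, then majority / locally-weighted / joint label fusion
   with a leave-one-out (LOO) evaluation harness.

Every stage is driven by a **synthetic thalamic-anatomy generator** with
known ground truth: per hemisphere a ~7.6 cm³ thalamus, a VLV cluster at
~15% of it, and a ~1% Vim placed flush against the inferior lateral VLV
border, plus an SWI-like intensity volume (hyperintense Vim, dark Vc/Vo,
pulvinar gradient, optional vessel artifacts, Gaussian noise) and
per-subject jitter for cohort experiments. See `docs/methods.md` for the
models, parameters and limitations.

Key quantities follow the field's conventions: volumes in mm³/cm³,
**normalized volume** as percent of the thalamus, overlap as the **Dice
coefficient** 2|A∩B|/(|A|+|B|), and boundary proximity as minimum
surface distance between boundary voxel centers.

## Worked example

```python
from vimloc import PhantomSpec, generate_subject
from vimloc.guiot_targeting import construct_guiot_target, sphere_roi
from vimloc.spatial_relations import relation_record
from vimloc.overlap_metrics import normalized_volume_pct, volume_mm3

subject = generate_subject(PhantomSpec(), seed=7)
vim = subject.mask("vim", "right")
vlv = subject.mask("vlv", "right")
thalamus = subject.mask("thalamus", "right")

print(f"Vim volume: {volume_mm3(vim):.1f} mm3 "
      f"({normalized_volume_pct(vim, thalamus):.2f}% of thalamus)")
print(f"VLV volume: {volume_mm3(vlv) / 1000:.2f} cm3 "
      f"({normalized_volume_pct(vlv, thalamus):.1f}% of thalamus)")

rec = relation_record(vim, vlv, subject_id="S1", hemisphere="right")
print(f"Vim-in-VLV containment: {rec.containment_fraction:.2f}")
print(f"Vim centroid subregion of VLV: {rec.inner_centroid_subregion}")
print(f"VLV borders within 1 mm of the Vim: {sorted(rec.adjacent_to)}")

target = construct_guiot_target(subject.landmarks, "right")
print(f"Guiot target point: {target.point} mm")
sphere = sphere_roi(target.point, 2.0, subject.spec.grid)
print(f"2 mm target sphere inside the Vim: "
      f"{(sphere.data & vim.data).sum() / sphere.voxel_count:.0%}")
```

Output:

```
Vim volume: 78.9 mm3 (1.00% of thalamus)
VLV volume: 1.18 cm3 (15.0% of thalamus)
Vim-in-VLV containment: 1.00
Vim centroid subregion of VLV: inferior-lateral
VLV borders within 1 mm of the Vim: ['inferior-lateral', 'superior-lateral']
Guiot target point: (13.0, -18.75, 0.0) mm
2 mm target sphere inside the Vim: 46%
```

Reading: the phantom Vim occupies 1% of the thalamus (78.9 mm³), sits
entirely inside the motor cluster with its centroid in the VLV's
inferior-lateral subregion, and touches the VLV's lateral border — the
anatomical configuration in which direct and cluster-based Vim definitions
agree. The indirectly constructed Guiot point (11 mm lateral of the
2 mm ventricle wall, a quarter of the PC→AC distance anterior of PC, on
the AC-PC plane) lands inside the Vim, with about half of its 2 mm
isodose sphere covered by the nucleus.

A thin CLI wraps the library: `vimloc phantom`, `vimloc guiot`,
`vimloc subdivide`, `vimloc relate`, `vimloc overlap`, `vimloc report`,
`vimloc fuse`, `vimloc loo`, `vimloc convert`, `vimloc table validate`
(see `vimloc --help`).

The packaged cohort volume table (9 subjects × 2 hemispheres; manual Vim,
multi-atlas Vim and VLV volumes with their thalamus-normalized percents)
ships as `fixtures/table1.csv` and via `vimloc.table1_path()`.

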