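# sfproj — spherical frame projections for joint range of motion

`sfproj` visualises and quantifies the rotational range of motion (RoM) of a
joint with the **spherical frame projection (SFP)**: trace the endpoints of
the distal bone's anatomical coordinate system (ACS) axes on the unit sphere
and bound each axis's trace with a spherical polygon. It is aimed at
comparative biomechanists and clinicians who collect 3-DoF joint pose data
(motion capture, XROMM, or simulation) and need a representation that shows
the *interaction* of rotational degrees of freedom, which scalar per-axis
angle ranges cannot.

## The model

A joint pose is the rotation `R ∈ SO(3)` of the distal ACS relative to the
proximal ACS, with the null pose at `R = I`. Because each **row** of the
rotation matrix `^dACS R_pACS` is the endpoint of one distal frame axis
expressed in the proximal frame, plotting the rows of every pose in a RoM
dataset gives three point clouds on the unit sphere — the X, Y and Z **frame
traces**. The SFP bounds each cloud with a spherical polygon (here: patch
occupancy on a subdivided-icosahedron grid, default 1 280 patches, followed
by an outer-perimeter walk), yielding three regions that jointly constrain
the frame. A pose is *possibly* reachable only if all three axis endpoints
fall inside their polygons; the test is necessary, not sufficient, so a
path-connectivity check through the sampled poses
(`check_pose_path`) is provided to screen out assembled false positives.

For rig-based capture the package also implements the marker-to-joint
transform chain

```
pACS_T_base    = pACS_T_pPlate · pPlate_T_base
dACS_T_markers = dACS_T_dPlate · dPlate_T_markers
dACS_T_pACS    = dACS_T_markers · markers_T_base · (pACS_T_base)⁻¹
```

with landmark-based plate/bone frame fitting and exact orthogonalisation of
fitted axis triads by recursive cross-product averaging. A synthetic module
generates ground-truth RoM datasets (1/2/3-DoF boxes, coupled DoF) and full
virtual rig sessions (marker trajectories plus a nonlinear passive-torque
channel), so the whole pipeline is testable without captured data.

## Worked example

```python
from sfproj import (RomSpec, build_sfp, check_pose, from_euler, EulerSpec,
                    generate_rom, frame_trace, geodesic_extent)

data = generate_rom(RomSpec("two_dof", (30.0, 15.0, 0.0), "XYZ", grid_step=2.5))
print(f"dataset: {len(data)} poses")

trace = frame_trace(data)
print(f"Z-axis trace extent: {geodesic_extent(trace.clouds['Z']):.1f} deg")

sfp = build_sfp(data)
for axis, area in sfp.areas().items():
    print(f"{axis} polygon: {len(sfp.polygons[axis])} vertices, {area:.3f} sr")

probe = from_euler(EulerSpec("XYZ", (20.0, -10.0, 0.0)))
print("pose (20, -10, 0) inside:", check_pose(sfp, probe).inside)
probe2 = from_euler(EulerSpec("XYZ", (0.0, 45.0, 0.0)))
print("pose (0, 45, 0) inside:", check_pose(sfp, probe2).inside)
```

prints

```
dataset: 325 poses
Z-axis trace extent: 66.5 deg
X polygon: 22 vertices, 0.285 sr
Y polygon: 21 vertices, 0.273 sr
Z polygon: 32 vertices, 0.650 sr
pose (20, -10, 0) inside: {'X': True, 'Y': True, 'Z': True}
pose (0, 45, 0) inside: {'X': False, 'Y': True, 'Z': False}
```

A joint with independent ±30° / ±15° ranges about X and Y yields three
rectangular regions on the sphere. The Z polygon's sides span the two
ranges (60° and 30° of geodesic arc through the null pose; its corner-to-
corner trace extent is the 66.5° printed above), and its solid angle of
0.65 sr quantifies the reachable area of the Z axis. The first probe pose
lies inside all three polygons — within the sampled RoM — while 45° about Y
pushes the X and Z endpoints out of their regions.

The same pipeline is scriptable from a shell:

```sh
sfproj simulate --mode two_dof --half-ranges 30 15 0 --grid-step 5 \
       --noise-sd 0 --out-prefix sess
sfproj transform sess.tsv sess_rig.json sess_markers_local.csv --out poses.csv
sfproj project poses.csv --out sfp.json
sfproj render sfp.json --out sfp.png
```

which simulates a virtual rig session, recovers joint orientations from the
marker TSV through the transform chain, fits the SFP and renders the
three-polygon sphere (X red, Y green, Z blue) with the null-pose frame at
the centre.

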