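# Acquisition-geometry presets for the six full-length radiographic systems.
#
# The published spec sheet prints the two stand-off distances as "SID/SOD"
# with SID < SOD for every system, which is impossible under the stated
# definitions (the object must lie between source and detector).  The presets
# below therefore assign the larger of the two printed numbers to sid and the
# smaller to sod; see docs/methods.md for the discussion.
#
# segments / overlap_fraction (rotational) and slot_width (slot) are not part
# of the published parameters; they are simulator defaults.
#
# object_offset is the depth (mm) of the phantom midplane in front of the
# nominal object plane.  The published plane-mean bead diameters imply that
# the phantom sat well source-ward of sod on the rotational systems (e.g.
# GC85A epsilon 1.16/1.07 against sid/sod = 1.05 puts the bead midplane
# ~114 mm in front of the object plane); where the implied offset would
# push the lateral beads off the rendered field, a smaller value that keeps
# every bead on the detector is used instead.
"Eagle Eye":
  modality: slot
  sid: 1500.0
  sod: 1230.0
  pixel_spacing: 0.139
  detector_size: [8268, 3072]
  slot_width: 430.0
EOS:
  modality: slot
  sid: 1300.0
  sod: 987.0
  pixel_spacing: 0.179
  detector_size: [5518, 1896]
  slot_width: 340.0
GC85A:
  modality: rotational
  sid: 2054.0
  sod: 1959.0
  pixel_spacing: 0.14
  detector_size: [8701, 2928]
  segments: 3
  overlap_fraction: 0.2
  object_offset: 114.0
UDR780IPRO3F:
  modality: rotational
  sid: 1863.0
  sod: 1703.0
  pixel_spacing: 0.111
  detector_size: [10895, 3258]
  segments: 3
  overlap_fraction: 0.2
  object_offset: 0.0
DRX-Compass:
  modality: rotational
  sid: 999.0
  sod: 849.0
  pixel_spacing: 0.139
  detector_size: [9792, 3010]
  segments: 3
  overlap_fraction: 0.2
  object_offset: 40.0
DSI-DRP:
  modality: one_shot
  sid: 2100.0
  sod: 1900.0
  pixel_spacing: 0.139
  detector_size: [8704, 3702]
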