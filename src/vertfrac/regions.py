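"""Region label codes shared by volumes, material fields and meshes."""

OUTSIDE = 0
TRABECULAR = 1
CORTICAL = 2
SCREW = 3
FAILED = 4  # material fields only, never in volumes

#: Raw-HU threshold separating cortical (>= 700) from trabecular (< 700) bone.
HU_CORTICAL_THRESHOLD = 700.0

REGION_NAMES = {
    OUTSIDE: "outside",
    TRABECULAR: "trabecular",
    CORTICAL: "cortical",
    SCREW: "screw",
    FAILED: "failed",
}
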