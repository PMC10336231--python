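# Shrinkage-corrected volumes (mm^3) of areas Op5, Op6 and Op7 per
# hemisphere in ten postmortem brains, transcribed from the published
# per-brain volume table.
# Four typographic artifacts of the printed table were corrected:
#   - BC8 Op6 left  "1,236,78" -> 1236.78 (decimal comma)
#   - BC8 Op6 right "701,92"   -> 701.92  (decimal comma)
#   - BC10 row sum  "6,827,71" -> 6827.71 (decimal comma; sum column not stored)
#   - Op5 left SD   "305.971"  -> 305.97  (extra digit; SD not stored)
# Row sums, means and SDs are derived quantities and are recomputed by
# cytomap.volumetry.summarize rather than stored here.
brain_id,hemisphere,area,volume_mm3
BC4,left,Op5,880.64
BC4,right,Op5,673.62
BC4,left,Op6,862.81
BC4,right,Op6,582.65
BC4,left,Op7,337.48
BC4,right,Op7,280.21
BC5,left,Op5,918.83
BC5,right,Op5,362.48
BC5,left,Op6,1084.69
BC5,right,Op6,1488.09
BC5,left,Op7,181.44
BC5,right,Op7,671.16
BC6,left,Op5,1129.95
BC6,right,Op5,1032.09
BC6,left,Op6,1530.89
BC6,right,Op6,1039.16
BC6,left,Op7,681.33
BC6,right,Op7,564.37
BC7,left,Op5,905.44
BC7,right,Op5,1745.84
BC7,left,Op6,2324.69
BC7,right,Op6,1842.41
BC7,left,Op7,413.13
BC7,right,Op7,1254.46
BC8,left,Op5,1185.68
BC8,right,Op5,1052.69
BC8,left,Op6,1236.78
BC8,right,Op6,701.92
BC8,left,Op7,487.63
BC8,right,Op7,233.74
BC9,left,Op5,404.81
BC9,right,Op5,1038.41
BC9,left,Op6,774.47
BC9,right,Op6,781.92
BC9,left,Op7,438.48
BC9,right,Op7,177.97
BC10,left,Op5,1087.60
BC10,right,Op5,1234.67
BC10,left,Op6,2061.01
BC10,right,Op6,1204.37
BC10,left,Op7,578.37
BC10,right,Op7,661.69
BC12,left,Op5,1195.72
BC12,right,Op5,1029.52
BC12,left,Op6,700.63
BC12,right,Op6,1013.90
BC12,left,Op7,616.89
BC12,right,Op7,430.58
BC20,left,Op5,1453.47
BC20,right,Op5,1376.31
BC20,left,Op6,957.07
BC20,right,Op6,1078.14
BC20,left,Op7,704.52
BC20,right,Op7,499.13
BC21,left,Op5,1437.65
BC21,right,Op5,1883.46
BC21,left,Op6,1284.70
BC21,right,Op6,1660.74
BC21,left,Op7,813.97
BC21,right,Op7,324.63
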