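flight_id,camera,period,time_start,time_end,target,habitat,result,alt_min_m,alt_max_m
F01,still_photo,morning,09:03,09:26,people,grassland|mixed,confirmed,32,149
F01,still_photo,morning,09:03,09:26,fence,mixed,confirmed,40,175
F02,still_photo,morning,09:05,09:38,rhinoceros,forest,confirmed,57,57
F03,still_photo,morning,09:42,10:02,people,mixed|forest|grassland,confirmed,29,82
F03,still_photo,morning,09:42,10:02,fence,mixed,confirmed,42,72
F04,still_photo,morning,09:52,10:12,rhinoceros,forest,confirmed,31,137
F05,still_photo,midday,10:16,10:39,fence,mixed,confirmed,50,175
F05,still_photo,midday,10:16,10:39,people,grassland,confirmed,123,158
F06,still_photo,midday,11:22,11:43,rhinoceros,grassland|forest,confirmed,38,239
F07,still_photo,midday,13:14,13:56,people,forest,not_confirmed,,
F08,still_photo,evening,17:19,17:38,rhinoceros,forest,confirmed,82,82
F08,still_photo,evening,17:19,17:38,people,grassland|forest,not_confirmed,,
F08,still_photo,evening,17:19,17:38,fence,mixed,not_confirmed,,
F09,thermal_video,morning,07:51,08:11,fence,mixed|grassland,confirmed,27,155
F09,thermal_video,morning,07:51,08:11,people,mixed|grassland,confirmed,31,100
F10,thermal_video,morning,08:21,08:55,fence,mixed,confirmed,37,98
F10,thermal_video,morning,08:21,08:55,people,mixed,not_confirmed,,
F11,thermal_video,morning,08:27,08:56,fence,mixed,not_confirmed,,
F12,thermal_video,morning,09:25,10:03,fence,mixed,confirmed,48,54
F12,thermal_video,morning,09:25,10:03,people,mixed,not_confirmed,,
F13,thermal_video,midday,10:27,10:46,rhinoceros,forest,not_confirmed,,
F14,thermal_video,midday,10:40,11:07,rhinoceros,forest,not_confirmed,,
F15,thermal_video,midday,12:32,13:04,rhinoceros,forest|grassland,not_confirmed,,
F16,thermal_video,night,18:19,19:02,people,grassland|forest,confirmed,12,125
F16,thermal_video,night,18:19,19:02,fence,mixed,not_confirmed,,
F17,thermal_video,night,18:41,19:00,rhinoceros,forest,not_confirmed,,
F18,thermal_video,night,19:17,19:40,fence,mixed,not_confirmed,,
F18,thermal_video,night,19:17,19:40,people,grassland,confirmed,36,36
F19,thermal_video,night,19:27,19:45,rhinoceros,grassland,not_confirmed,,
F20,visual_video,midday,11:08,11:27,fence,mixed|forest|grassland,confirmed,10,17
F20,visual_video,midday,11:08,11:27,people,mixed|forest|grassland,confirmed,10,35
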