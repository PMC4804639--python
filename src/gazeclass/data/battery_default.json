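{
 "screen": {
  "width_px": 1280,
  "height_px": 1024,
  "sample_rate_hz": 50
 },
 "stimuli": [
  {
   "id": "A",
   "name": "human face (still image)",
   "duration_s": 7.0,
   "aois": [
    {
     "id": "eyes",
     "role": "aoi1",
     "rect": [
      440,
      260,
      840,
      460
     ],
     "direction": "asd_lower"
    },
    {
     "id": "mouth",
     "role": "aoi2",
     "rect": [
      480,
      560,
      800,
      720
     ],
     "direction": "asd_higher"
    }
   ]
  },
  {
   "id": "B",
   "name": "human face (blinking)",
   "duration_s": 7.0,
   "aois": [
    {
     "id": "eyes",
     "role": "aoi1",
     "rect": [
      440,
      260,
      840,
      460
     ],
     "direction": "asd_lower"
    },
    {
     "id": "mouth",
     "role": "aoi2",
     "rect": [
      480,
      560,
      800,
      720
     ],
     "direction": "asd_higher"
    }
   ]
  },
  {
   "id": "C",
   "name": "human face (mouth moving)",
   "duration_s": 4.0,
   "aois": [
    {
     "id": "eyes",
     "role": "aoi1",
     "rect": [
      440,
      260,
      840,
      460
     ],
     "direction": "asd_lower"
    },
    {
     "id": "mouth",
     "role": "aoi2",
     "rect": [
      480,
      560,
      800,
      720
     ],
     "direction": "asd_higher"
    }
   ]
  },
  {
   "id": "D",
   "name": "human face (silent)",
   "duration_s": 3.0,
   "aois": [
    {
     "id": "eyes",
     "role": "aoi1",
     "rect": [
      440,
      260,
      840,
      460
     ],
     "direction": "asd_lower"
    },
    {
     "id": "mouth",
     "role": "aoi2",
     "rect": [
      480,
      560,
      800,
      720
     ],
     "direction": "asd_higher"
    }
   ]
  },
  {
   "id": "E",
   "name": "human face (talking)",
   "duration_s": 7.0,
   "aois": [
    {
     "id": "eyes",
     "role": "aoi1",
     "rect": [
      440,
      260,
      840,
      460
     ],
     "direction": "asd_lower"
    },
    {
     "id": "mouth",
     "role": "aoi2",
     "rect": [
      480,
      560,
      800,
      720
     ],
     "direction": "asd_higher"
    }
   ]
  },
  {
   "id": "F",
   "name": "biological motion (upright vs inverted)",
   "duration_s": 20.0,
   "aois": [
    {
     "id": "upright",
     "role": "aoi1",
     "rect": [
      40,
      112,
      600,
      912
     ],
     "direction": "asd_lower"
    },
    {
     "id": "inverted",
     "role": "aoi2",
     "rect": [
      680,
      112,
      1240,
      912
     ],
     "direction": "asd_higher"
    }
   ]
  },
  {
   "id": "G",
   "name": "people and geometry (same size)",
   "duration_s": 16.0,
   "aois": [
    {
     "id": "people",
     "role": "aoi1",
     "rect": [
      40,
      112,
      600,
      912
     ],
     "direction": "asd_lower"
    },
    {
     "id": "geometry",
     "role": "aoi2",
     "rect": [
      680,
      112,
      1240,
      912
     ],
     "direction": "asd_higher"
    }
   ]
  },
  {
   "id": "H",
   "name": "people and geometry (small window)",
   "duration_s": 16.0,
   "aois": [
    {
     "id": "geometry",
     "role": "aoi1",
     "rect": [
      880,
      640,
      1240,
      944
     ],
     "direction": "asd_higher"
    }
   ]
  }
 ]
}
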