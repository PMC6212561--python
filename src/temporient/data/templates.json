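{
  "slots": {
    "noun": [
      "dinner", "coffee", "exam", "beach", "weather", "traffic", "music",
      "homework", "assignment", "weekend", "birthday", "holiday", "movie",
      "kitchen", "essay", "garden", "laundry", "haircut", "deadline", "lecture"
    ]
  },
  "templates": {
    "past": [
      "I went to the {noun}",
      "thought about my {noun} earlier",
      "we talked about the {noun}",
      "remembered my {noun}",
      "slept badly last night",
      "I missed the bus",
      "slept in",
      "napped"
    ],
    "present": [
      "I am eating {noun}",
      "thinking about the {noun}",
      "watching a {noun} with my friend",
      "just listening to {noun}",
      "she is cooking {noun}",
      "working on my {noun}",
      "eating",
      "relaxing"
    ],
    "future": [
      "I will go to the {noun}",
      "we should visit the {noun} soon",
      "might go to the {noun} later",
      "I will cook {noun} for my friend",
      "will plan for the future",
      "she might call me about the {noun}",
      "will sleep",
      "might nap"
    ],
    "other": [
      "not much",
      "just here and there",
      "so so",
      "out and about",
      "not sure really",
      "all good",
      "same as always",
      "ok",
      "?"
    ],
    "ambiguous": [
      "I went to the {noun} and will go again",
      "I am eating {noun} and will study later",
      "thought about the {noun} I am making",
      "in 2019 , I will have remembered this {noun}",
      "we talked about the {noun} and she is happy",
      "was eating {noun}"
    ]
  },
  "fillers": {
    "past": [
      " and then we walked home",
      " after we visited the {noun}",
      " because it rained a lot",
      " and I felt tired"
    ],
    "present": [
      " while drinking coffee",
      " and watching the {noun}",
      " at the {noun} right now",
      " and it is nice"
    ],
    "future": [
      " and then we might see a {noun} too",
      " and might buy a {noun} later",
      " because we will meet soon"
    ],
    "other": [
      " and so on",
      " here and there",
      " but not much",
      " not really"
    ],
    "ambiguous": [
      " and so on",
      " here and there",
      " but not much",
      " not really"
    ]
  }
}
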