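taxon,rank,group,year,count
Balaenoptera acutorostrata,species,cetacean,2010,1
Balaenoptera acutorostrata,species,cetacean,2011,1
Balaenoptera physalus,species,cetacean,2003,1
Balaenoptera physalus,species,cetacean,2004,2
Balaenoptera physalus,species,cetacean,2007,2
Balaenoptera physalus,species,cetacean,2008,3
Balaenoptera physalus,species,cetacean,2011,4
Balaenoptera physalus,species,cetacean,2012,2
Delphinidae (undetermined),genus_or_higher,cetacean,2003,40
Delphinidae (undetermined),genus_or_higher,cetacean,2004,30
Delphinidae (undetermined),genus_or_higher,cetacean,2005,36
Delphinidae (undetermined),genus_or_higher,cetacean,2006,22
Delphinidae (undetermined),genus_or_higher,cetacean,2007,15
Delphinidae (undetermined),genus_or_higher,cetacean,2008,9
Delphinidae (undetermined),genus_or_higher,cetacean,2009,9
Delphinidae (undetermined),genus_or_higher,cetacean,2010,6
Delphinidae (undetermined),genus_or_higher,cetacean,2011,16
Delphinidae (undetermined),genus_or_higher,cetacean,2012,8
Delphinus delphis,species,cetacean,2003,56
Delphinus delphis,species,cetacean,2004,61
Delphinus delphis,species,cetacean,2005,109
Delphinus delphis,species,cetacean,2006,53
Delphinus delphis,species,cetacean,2007,51
Delphinus delphis,species,cetacean,2008,56
Delphinus delphis,species,cetacean,2009,40
Delphinus delphis,species,cetacean,2010,39
Delphinus delphis,species,cetacean,2011,72
Delphinus delphis,species,cetacean,2012,57
Globicephala melas,species,cetacean,2003,6
Globicephala melas,species,cetacean,2004,5
Globicephala melas,species,cetacean,2005,7
Globicephala melas,species,cetacean,2006,1
Globicephala melas,species,cetacean,2007,1
Globicephala melas,species,cetacean,2008,2
Globicephala melas,species,cetacean,2009,1
Globicephala melas,species,cetacean,2010,2
Globicephala melas,species,cetacean,2011,1
Globicephala melas,species,cetacean,2012,2
Grampus griseus,species,cetacean,2003,2
Grampus griseus,species,cetacean,2004,1
Grampus griseus,species,cetacean,2005,7
Grampus griseus,species,cetacean,2006,3
Grampus griseus,species,cetacean,2007,1
Grampus griseus,species,cetacean,2008,7
Grampus griseus,species,cetacean,2009,2
Grampus griseus,species,cetacean,2010,1
Grampus griseus,species,cetacean,2011,2
Grampus griseus,species,cetacean,2012,4
Hyperoodon ampullatus,species,cetacean,2011,1
Lagenorhynchus acutus,species,cetacean,2006,1
Lagenorhynchus acutus,species,cetacean,2007,2
Lagenorhynchus acutus,species,cetacean,2011,1
Lagenorhynchus acutus,species,cetacean,2012,1
Orcinus orca,species,cetacean,2004,1
Phocoena phocoena,species,cetacean,2003,18
Phocoena phocoena,species,cetacean,2004,13
Phocoena phocoena,species,cetacean,2005,12
Phocoena phocoena,species,cetacean,2006,15
Phocoena phocoena,species,cetacean,2007,20
Phocoena phocoena,species,cetacean,2008,23
Phocoena phocoena,species,cetacean,2009,9
Phocoena phocoena,species,cetacean,2010,10
Phocoena phocoena,species,cetacean,2011,15
Phocoena phocoena,species,cetacean,2012,11
Physeter macrocephalus,species,cetacean,2004,2
Physeter macrocephalus,species,cetacean,2007,1
Stenella coeruleoalba,species,cetacean,2003,1
Stenella coeruleoalba,species,cetacean,2005,7
Stenella coeruleoalba,species,cetacean,2006,9
Stenella coeruleoalba,species,cetacean,2007,8
Stenella coeruleoalba,species,cetacean,2008,4
Stenella coeruleoalba,species,cetacean,2009,5
Stenella coeruleoalba,species,cetacean,2010,9
Stenella coeruleoalba,species,cetacean,2011,6
Stenella coeruleoalba,species,cetacean,2012,3
Stenella frontalis,species,cetacean,2005,1
Tursiops truncatus,species,cetacean,2003,6
Tursiops truncatus,species,cetacean,2004,2
Tursiops truncatus,species,cetacean,2005,7
Tursiops truncatus,species,cetacean,2006,6
Tursiops truncatus,species,cetacean,2007,4
Tursiops truncatus,species,cetacean,2008,5
Tursiops truncatus,species,cetacean,2009,3
Tursiops truncatus,species,cetacean,2010,8
Tursiops truncatus,species,cetacean,2011,3
Tursiops truncatus,species,cetacean,2012,3
Ziphius cavirostris,species,cetacean,2007,1
Ziphius cavirostris,species,cetacean,2009,1
Mysticeti (undetermined),genus_or_higher,cetacean,2005,1
Mysticeti (undetermined),genus_or_higher,cetacean,2006,4
Odontoceti (undetermined),genus_or_higher,cetacean,2003,5
Odontoceti (undetermined),genus_or_higher,cetacean,2004,1
Odontoceti (undetermined),genus_or_higher,cetacean,2005,1
Odontoceti (undetermined),genus_or_higher,cetacean,2006,3
Odontoceti (undetermined),genus_or_higher,cetacean,2007,1
Cetacea (undetermined),genus_or_higher,cetacean,2006,3
Cetacea (undetermined),genus_or_higher,cetacean,2007,3
Cetacea (undetermined),genus_or_higher,cetacean,2008,2
Cetacea (undetermined),genus_or_higher,cetacean,2011,1
Cystophora cristata,species,pinniped,2005,1
Cystophora cristata,species,pinniped,2006,3
Halichoerus grypus,species,pinniped,2003,20
Halichoerus grypus,species,pinniped,2004,29
Halichoerus grypus,species,pinniped,2005,41
Halichoerus grypus,species,pinniped,2006,37
Halichoerus grypus,species,pinniped,2007,51
Halichoerus grypus,species,pinniped,2008,41
Halichoerus grypus,species,pinniped,2009,37
Halichoerus grypus,species,pinniped,2010,13
Halichoerus grypus,species,pinniped,2011,34
Halichoerus grypus,species,pinniped,2012,24
Phoca groenlandica,species,pinniped,2004,1
Phoca vitulina,species,pinniped,2003,1
Phoca vitulina,species,pinniped,2004,1
Phoca vitulina,species,pinniped,2005,2
Phoca vitulina,species,pinniped,2006,1
Phoca vitulina,species,pinniped,2007,1
Phoca vitulina,species,pinniped,2008,1
Phoca vitulina,species,pinniped,2010,2
Phoca vitulina,species,pinniped,2011,3
Pusa hispida,species,pinniped,2005,1
Pusa hispida,species,pinniped,2009,1
Phocidae (undetermined),genus_or_higher,pinniped,2003,5
Phocidae (undetermined),genus_or_higher,pinniped,2005,7
Phocidae (undetermined),genus_or_higher,pinniped,2006,4
Phocidae (undetermined),genus_or_higher,pinniped,2007,13
Phocidae (undetermined),genus_or_higher,pinniped,2008,4
Phocidae (undetermined),genus_or_higher,pinniped,2009,5
Phocidae (undetermined),genus_or_higher,pinniped,2011,2
Phocidae (undetermined),genus_or_higher,pinniped,2012,1
Unknown,unknown,unknown,2012,1
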